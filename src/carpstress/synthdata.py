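"""Synthetic Ct-table generator with known ground truth.

The generator emulates the study design — 2 groups x 4 fish x 4 brain
regions x 26 genes x 3 technical replicates — on the Ct (threshold cycle)
scale.  The measurement model is additive on the Ct scale, which is the
log-expression scale for an amplification efficiency E (one cycle equals
a factor E in template amount):

    ct[a, r, g, rep] = baseline[g, r]
                       - gamma[a]                       (animal effect)
                       - x[a] * effect_log2[g, r] / log2(E)
                       - b[a, r, g]                     (biological noise)
                       + t[a, r, g, rep]                (technical noise)

where ``x[a]`` is 1 for stressed animals and 0 for controls, so a positive
``effect_log2`` (up-regulation) lowers the stressed-group Ct.  The animal
effect ``gamma`` shifts all genes of an animal together (RNA input /
reverse-transcription yield) and is removed downstream by reference-gene
normalization.  Undetected wells are recorded as missing, not censored at
cycle 40.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from carpstress.panel import (
    GROUPS,
    REGIONS,
    REFERENCE_CANDIDATES,
    GenePanel,
    default_panel,
)

CT_COLUMNS = ["animal_id", "region", "group", "gene", "replicate", "ct"]

#: The most stable reference trio: region-constant baseline, minimal
#: biological noise, so expression-stability ranking recovers it.
STABLE_REFERENCES = ("bactin", "eif4e", "ef")

#: Default gene x region log2 fold changes (stressed vs control), chosen to
#: mirror the qualitative study outcome: c-fos induction in the telencephalon,
#: opposite crf1/crf2 shifts relative to crh-bp, pomc1/pomc2 effects in the
#: optic tectum and rhombencephalon, and gabaa/serotr down-shifts.  Reference
#: candidates are stable (no entry = effect 0).
DEFAULT_EFFECTS_LOG2: dict[tuple[str, str], float] = {
    ("c-fos", "tel"): 2.0,
    ("c-fos", "opt"): -1.5,
    ("crf1", "tel"): -1.5,
    ("crf1", "hyp"): 1.5,
    ("crf2", "tel"): -2.0,
    ("pomc2", "tel"): 2.0,
    ("pomc2", "opt"): 2.0,
    ("pomc1", "opt"): 1.5,
    ("pomc1", "rho"): 1.7,
    ("gabaa", "opt"): -1.6,
    ("serotr", "tel"): -1.5,
    ("serotr", "rho"): 1.5,
    ("prolr", "opt"): -1.0,
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic Ct measurement model.

    Standard deviations are in cycles; ``effect_log2`` is the log2 fold
    change of stressed vs control expression per (gene, region).
    """

    n_per_group: int = 4
    regions: tuple[str, ...] = REGIONS
    panel: GenePanel = field(default_factory=default_panel)
    n_tech_reps: int = 3
    baseline_ct: dict[tuple[str, str], float] = field(default_factory=dict)
    effect_log2: dict[tuple[str, str], float] = field(default_factory=dict)
    sd_animal: float = 0.3
    sd_biological: float = 0.5
    sd_biological_overrides: dict[str, float] = field(default_factory=dict)
    sd_technical: float = 0.2
    efficiency: float = 2.0
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("invalid config: n_per_group must be >= 2")
        for name in ("sd_animal", "sd_biological", "sd_technical"):
            if getattr(self, name) < 0:
                raise ValueError(f"invalid config: {name} must be >= 0")
        if any(v < 0 for v in self.sd_biological_overrides.values()):
            raise ValueError("invalid config: sd_biological_overrides must be >= 0")
        if not (1.0 < self.efficiency <= 2.0):
            raise ValueError("invalid config: efficiency must be in (1, 2]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("invalid config: missing_rate must be in [0, 1)")
        if self.n_tech_reps < 1:
            raise ValueError("invalid config: n_tech_reps must be >= 1")
        if not self.regions:
            raise ValueError("invalid config: regions must be non-empty")
        genes = set(self.panel.genes)
        for g, r in self.baseline_ct:
            if g not in genes or r not in self.regions:
                raise ValueError(f"invalid config: baseline_ct key ({g}, {r}) unknown")
        for g, r in self.effect_log2:
            if g not in genes or r not in self.regions:
                raise ValueError(f"invalid config: effect_log2 key ({g}, {r}) unknown")

    def sd_biological_for(self, gene: str) -> float:
        return self.sd_biological_overrides.get(gene, self.sd_biological)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["panel"] = {
            "reference_candidates": list(self.panel.reference_candidates),
            "targets": list(self.panel.targets),
            "ratio_pairs": [list(p) for p in self.panel.ratio_pairs],
        }
        d["baseline_ct"] = {f"{g}|{r}": float(v) for (g, r), v in self.baseline_ct.items()}
        d["effect_log2"] = {f"{g}|{r}": float(v) for (g, r), v in self.effect_log2.items()}
        d["regions"] = list(self.regions)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated table, for recovery tests."""

    effect_log2: pd.DataFrame  # columns: gene, region, effect_log2
    animal_effect: pd.DataFrame  # columns: animal_id, group, gamma
    variance_components: dict[str, float]

    def effect(self, gene: str, region: str) -> float:
        m = (self.effect_log2["gene"] == gene) & (self.effect_log2["region"] == region)
        return float(self.effect_log2.loc[m, "effect_log2"].iloc[0])


def default_study_config(seed: int = 0, baseline_range: tuple[float, float] = (18.0, 30.0)) -> SyntheticConfig:
    """Config matching the study design: 8 animals, 4 regions, 26 genes, 3 reps.

    Per-gene x region baseline Cts are drawn once (uniformly over
    ``baseline_range``) at config creation and then fixed.  Reference
    candidates have zero treatment effect everywhere and a region-constant
    baseline (reference genes are, by definition, expressed uniformly
    across tissue); the most stable trio additionally carries minimal
    biological noise while the remaining candidates get an intermediate
    level, emulating the usual outcome that only a subset of a candidate
    panel is truly stable.
    """
    panel = default_panel()
    rng = np.random.default_rng(seed)
    baselines: dict[tuple[str, str], float] = {}
    for g in panel.genes:
        if g in REFERENCE_CANDIDATES:
            level = float(rng.uniform(*baseline_range))
            for r in REGIONS:
                baselines[(g, r)] = level
        else:
            for r in REGIONS:
                baselines[(g, r)] = float(rng.uniform(*baseline_range))
    overrides = {g: 0.35 for g in REFERENCE_CANDIDATES}
    overrides.update({g: 0.05 for g in STABLE_REFERENCES})
    cfg = SyntheticConfig(
        panel=panel,
        baseline_ct=baselines,
        effect_log2=dict(DEFAULT_EFFECTS_LOG2),
        sd_biological_overrides=overrides,
        seed=seed,
    )
    cfg.validate()
    return cfg


def generate_ct_table(config: SyntheticConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw one synthetic Ct table plus its ground-truth record.

    Returns a long-format table with columns ``animal_id, region, group,
    gene, replicate, ct`` (ct is NaN for undetected wells) and a
    :class:`SyntheticTruth`.  Identical config (including seed) gives an
    identical table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.panel.genes
    log2_eff = np.log2(config.efficiency)

    animals = [f"ctrl{i + 1}" for i in range(config.n_per_group)] + [
        f"str{i + 1}" for i in range(config.n_per_group)
    ]
    groups = ["control"] * config.n_per_group + ["stressed"] * config.n_per_group
    x = np.array([0.0] * config.n_per_group + [1.0] * config.n_per_group)

    gamma = rng.normal(0.0, config.sd_animal, size=len(animals))

    rows = []
    for ia, (animal, grp) in enumerate(zip(animals, groups)):
        for region in config.regions:
            for gene in genes:
                base = config.baseline_ct.get((gene, region), 24.0)
                eff = config.effect_log2.get((gene, region), 0.0)
                bio = rng.normal(0.0, config.sd_biological_for(gene)) if config.sd_biological_for(gene) > 0 else 0.0
                true_ct = base - gamma[ia] - x[ia] * eff / log2_eff - bio
                for rep in range(1, config.n_tech_reps + 1):
                    tech = rng.normal(0.0, config.sd_technical) if config.sd_technical > 0 else 0.0
                    ct = true_ct + tech
                    if config.missing_rate > 0 and rng.uniform() < config.missing_rate:
                        ct = np.nan
                    rows.append((animal, region, grp, gene, rep, ct))

    table = pd.DataFrame(rows, columns=CT_COLUMNS)

    truth_effects = pd.DataFrame(
        [
            (g, r, config.effect_log2.get((g, r), 0.0))
            for g in genes
            for r in config.regions
        ],
        columns=["gene", "region", "effect_log2"],
    )
    truth_animals = pd.DataFrame(
        {"animal_id": animals, "group": groups, "gamma": gamma}
    )
    truth = SyntheticTruth(
        effect_log2=truth_effects,
        animal_effect=truth_animals,
        variance_components={
            "sd_animal": config.sd_animal,
            "sd_biological": config.sd_biological,
            "sd_technical": config.sd_technical,
        },
    )
    return table, truth


def write_ct_csv(table: pd.DataFrame, path) -> None:
    """Write a Ct table as CSV; missing wells become empty fields."""
    table.to_csv(path, index=False, float_format="%.6f")


def write_truth_csv(truth: SyntheticTruth, path) -> None:
    truth.effect_log2.to_csv(path, index=False)
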