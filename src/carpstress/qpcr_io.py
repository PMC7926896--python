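"""Ct-table I/O, validation, and the end-to-end per-region pipeline.

The pipeline mirrors the study's reporting: analyses are run
independently per brain region.  For each region it produces the
reference-gene stability ranking (selection is per dataset by default,
as one reference set serves all regions), normalized expression with
group summaries, gene-pair ratio tests with BCa intervals, the
hierarchical-model summary table (point estimate, posterior SD, 95%
credible interval, posterior p per gene), and PCAs for the configured
gene subsets.  All stochastic steps take seeds derived from a single
pipeline seed, and every seed is recorded in the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from carpstress import groupstats, hiermodel, multivar, normexpr, refstab
from carpstress.panel import (
    FINAL_PCA_GENES,
    GROUPS,
    HPI_GENES,
    IEG_GENES,
    NEURO_GENES,
    GenePanel,
)

logger = logging.getLogger(__name__)

CT_COLUMNS = ["animal_id", "region", "group", "gene", "replicate", "ct"]
CT_RANGE = (0.0, 45.0)

DEFAULT_PCA_SUBSETS: dict[str, tuple[str, ...]] = {
    "ieg": IEG_GENES,
    "hpi": HPI_GENES,
    "neuro": NEURO_GENES,
    "final": FINAL_PCA_GENES,
}


@dataclass
class PipelineSettings:
    n_reference: int = 3
    per_region_reference: bool = False
    efficiency: float = 2.0
    log_base: float = 2.0
    nf_per_group: bool = False
    qc_replicate_sd: float = 0.5
    bootstrap_n: int = 2000
    bootstrap_level: float = 0.95
    chains: int = 4
    iters: int = 4000
    warmup: int = 2000
    n_posterior_rep: int = 200
    pca_subsets: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PCA_SUBSETS)
    )
    pca_scale: bool = True
    alpha: float = 0.05
    seed: int = 0


@dataclass
class RegionReport:
    region: str
    group_summary: pd.DataFrame
    ratio_tests: pd.DataFrame
    hier_table: pd.DataFrame
    hier_converged: bool
    pca: dict[str, multivar.PCAResult]
    pca_cos2: dict[str, pd.DataFrame]
    pca_ellipses: dict[str, pd.DataFrame]
    ppc_band_coverage: float
    seeds: dict[str, int]


@dataclass
class ReportBundle:
    stability: refstab.StabilityRanking
    reference_genes: list[str]
    normalized: pd.DataFrame
    regions: dict[str, RegionReport]
    settings: PipelineSettings
    seeds: dict[str, int]
    warnings: list[str] = field(default_factory=list)


def validate_ct_table(df: pd.DataFrame, panel: GenePanel) -> pd.DataFrame:
    """Validate a long-format Ct table against the schema invariants."""
    missing_cols = [c for c in CT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"Ct table missing columns: {missing_cols}")
    df = df[CT_COLUMNS].copy()
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")

    key = ["animal_id", "region", "gene", "replicate"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        first = df.loc[dup, key].iloc[0].tolist()
        raise ValueError(f"duplicate (animal, region, gene, replicate) key: {first}")

    bad_group = set(df["group"]) - set(GROUPS)
    if bad_group:
        raise ValueError(f"unknown group label(s): {sorted(bad_group)}")
    multi = df.groupby("animal_id")["group"].nunique()
    if (multi > 1).any():
        raise ValueError(
            f"animal(s) assigned to more than one group: {list(multi[multi > 1].index)}"
        )

    detected = df["ct"].notna()
    out_of_range = detected & ~((df["ct"] > CT_RANGE[0]) & (df["ct"] <= CT_RANGE[1]))
    if out_of_range.any():
        row = int(np.flatnonzero(out_of_range.to_numpy())[0])
        raise ValueError(
            f"ct value {df['ct'].iloc[row]} at row {row} outside ({CT_RANGE[0]}, {CT_RANGE[1]}]"
        )

    absent = set(panel.genes) - set(df["gene"])
    if absent:
        logger.warning("Ct table missing panel genes: %s", sorted(absent))
    return df


def read_ct_table(path, panel: GenePanel) -> pd.DataFrame:
    """Read and validate a long-format Ct CSV (missing wells = empty field)."""
    df = pd.read_csv(path)
    return validate_ct_table(df, panel)


def _derive_seeds(seed: int, regions: list[str]) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    names = ["bootstrap"] + [f"gibbs_{r}" for r in regions] + [f"ppc_{r}" for r in regions]
    vals = rng.integers(0, 2**31 - 1, size=len(names))
    return {n: int(v) for n, v in zip(names, vals)}


def select_reference_genes(
    ct: pd.DataFrame,
    panel: GenePanel,
    settings: PipelineSettings,
    region: str | None = None,
) -> refstab.StabilityRanking:
    """geNorm selection over the panel's candidates, per dataset or region."""
    sub = ct if region is None else ct[ct["region"] == region]
    mean_ct = normexpr.collapse_replicates(sub, settings.qc_replicate_sd)
    cand = mean_ct[mean_ct["gene"].isin(panel.reference_candidates)]
    rq = refstab.stability_relative_quantities(cand, efficiency=settings.efficiency)
    return refstab.genorm_select(rq, n_keep=settings.n_reference)


def run_pipeline(
    ct: pd.DataFrame,
    panel: GenePanel,
    settings: PipelineSettings | None = None,
) -> ReportBundle:
    """Run the complete analysis; a pure function of (ct, panel, settings)."""
    settings = settings or PipelineSettings()
    ct = validate_ct_table(ct, panel)
    for grp in GROUPS:
        n = ct.loc[ct["group"] == grp, "animal_id"].nunique()
        if n < 2:
            raise ValueError(f"need >= 2 animals per group; group {grp!r} has {n}")
    n_cand = ct.loc[ct["gene"].isin(panel.reference_candidates), "gene"].nunique()
    if n_cand < 3:
        raise ValueError(f"need >= 3 measured reference candidates, found {n_cand}")

    regions = sorted(ct["region"].unique())
    seeds = _derive_seeds(settings.seed, regions)
    warnings: list[str] = []

    stability = select_reference_genes(ct, panel, settings)
    reference_genes = list(stability.selected)

    norm_settings = normexpr.NormalizationSettings(
        efficiency=settings.efficiency,
        log_base=settings.log_base,
        nf_per_group=settings.nf_per_group,
        qc_replicate_sd=settings.qc_replicate_sd,
    )
    normalized = normexpr.normalized_expression(ct, reference_genes, norm_settings)

    region_reports: dict[str, RegionReport] = {}
    for region in regions:
        sub = normalized[normalized["region"] == region]
        if sub["group"].nunique() < 2:
            msg = f"region {region!r} missing a group; skipped"
            warnings.append(msg)
            logger.warning(msg)
            continue
        try:
            region_reports[region] = _run_region(
                region, sub, normalized, panel, settings, seeds
            )
        except Exception as err:  # noqa: BLE001 - stage name added, then re-raised
            raise RuntimeError(f"pipeline stage failed in region {region!r}: {err}") from err

    return ReportBundle(
        stability=stability,
        reference_genes=reference_genes,
        normalized=normalized,
        regions=region_reports,
        settings=settings,
        seeds=seeds,
        warnings=warnings,
    )


def _run_region(
    region: str,
    sub: pd.DataFrame,
    normalized: pd.DataFrame,
    panel: GenePanel,
    settings: PipelineSettings,
    seeds: dict[str, int],
) -> RegionReport:
    summary = normexpr.group_summary(sub, log_base=settings.log_base)

    ratios = pd.concat(
        [
            groupstats.pair_log_ratio(sub, pair)
            for pair in panel.ratio_pairs
            if {pair[0], pair[1]} <= set(sub["gene"])
        ],
        ignore_index=True,
    )
    ratio_tests = groupstats.ratio_group_tests(
        ratios,
        B=settings.bootstrap_n,
        level=settings.bootstrap_level,
        seed=seeds["bootstrap"],
    )

    data = hiermodel.build_model_data(normalized, region)
    fit = hiermodel.fit_gibbs(
        data,
        chains=settings.chains,
        iters=settings.iters,
        warmup=settings.warmup,
        seed=seeds[f"gibbs_{region}"],
    )
    ppc = hiermodel.posterior_predictive(
        fit, data, n_rep=settings.n_posterior_rep, seed=seeds[f"ppc_{region}"]
    )
    in_band = (
        (ppc.observed_quantiles >= ppc.rep_quantile_lo)
        & (ppc.observed_quantiles <= ppc.rep_quantile_hi)
    ).mean()

    wide = sub.pivot_table(index="animal_id", columns="gene", values="log_norm")
    groups = sub[["animal_id", "group"]].drop_duplicates().set_index("animal_id")["group"]
    pca_results: dict[str, multivar.PCAResult] = {}
    pca_cos2: dict[str, pd.DataFrame] = {}
    pca_ellipses: dict[str, pd.DataFrame] = {}
    for name, genes in settings.pca_subsets.items():
        present = [g for g in genes if g in wide.columns]
        if len(present) < 2:
            logger.warning("PCA subset %r has < 2 genes in region %s; skipped", name, region)
            continue
        block = wide[present].dropna(axis=0)
        try:
            res = multivar.fit_pca(block, scale=settings.pca_scale)
        except ValueError as err:
            logger.warning("PCA subset %r skipped in region %s: %s", name, region, err)
            continue
        pca_results[name] = res
        pca_cos2[name] = multivar.variable_cos2(res)
        pca_ellipses[name] = multivar.ellipse_frame(
            multivar.group_ellipses(res.scores, groups.loc[block.index])
        )

    return RegionReport(
        region=region,
        group_summary=summary,
        ratio_tests=ratio_tests,
        hier_table=fit.summaries,
        hier_converged=fit.converged,
        pca=pca_results,
        pca_cos2=pca_cos2,
        pca_ellipses=pca_ellipses,
        ppc_band_coverage=float(in_band),
        seeds={
            "bootstrap": seeds["bootstrap"],
            "gibbs": seeds[f"gibbs_{region}"],
            "ppc": seeds[f"ppc_{region}"],
        },
    )


def write_report(bundle: ReportBundle, outdir) -> None:
    """Write the report artifacts: CSV tables per stage + a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.stability.to_frame().to_csv(outdir / "stability.csv", index=False)
    bundle.normalized.to_csv(outdir / "normalized_expression.csv", index=False)
    for region, rep in bundle.regions.items():
        rdir = outdir / region
        rdir.mkdir(exist_ok=True)
        rep.group_summary.to_csv(rdir / "group_summary.csv", index=False)
        rep.ratio_tests.to_csv(rdir / "ratio_tests.csv", index=False)
        rep.hier_table.to_csv(rdir / "hierarchical_table.csv", index=False)
        for name, res in rep.pca.items():
            pd.DataFrame(
                {
                    "component": [f"Dim{i + 1}" for i in range(res.n_components)],
                    "eigenvalue": res.eigenvalues,
                    "percent_variance": res.percent_variance,
                }
            ).to_csv(rdir / f"pca_{name}_eigen.csv", index=False)
            res.scores.to_csv(rdir / f"pca_{name}_scores.csv")
            res.variable_coords.to_csv(rdir / f"pca_{name}_coords.csv")
            rep.pca_cos2[name].to_csv(rdir / f"pca_{name}_cos2.csv")
            rep.pca_ellipses[name].to_csv(rdir / f"pca_{name}_ellipses.csv", index=False)
    summary = {
        "reference_genes": bundle.reference_genes,
        "seed": bundle.settings.seed,
        "seeds": bundle.seeds,
        "settings": {
            "n_reference": bundle.settings.n_reference,
            "efficiency": bundle.settings.efficiency,
            "log_base": bundle.settings.log_base,
            "bootstrap_n": bundle.settings.bootstrap_n,
            "bootstrap_level": bundle.settings.bootstrap_level,
            "chains": bundle.settings.chains,
            "iters": bundle.settings.iters,
            "warmup": bundle.settings.warmup,
            "pca_scale": bundle.settings.pca_scale,
            "alpha": bundle.settings.alpha,
        },
        "regions": {
            r: {
                "hier_converged": rep.hier_converged,
                "ppc_band_coverage": rep.ppc_band_coverage,
                "pca_percent_variance_dim12": {
                    name: float(res.percent_variance[:2].sum())
                    for name, res in rep.pca.items()
                },
                "seeds": rep.seeds,
            }
            for r, rep in bundle.regions.items()
        },
        "warnings": bundle.warnings,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
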