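"""Gene panel declarations for the carp brain distress study.

The panel comprises 26 genes: 8 candidate reference genes (of which three
are selected by expression-stability ranking) and 21 target genes spanning
immediate early genes (IEGs), hypothalamus-pituitary-interrenal (HPI) axis
genes and neurotransmitter-pathway genes.  Three genes (egr-1, palld,
gapdh) are both reference candidates and targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field


REFERENCE_CANDIDATES = (
    "18s-rna",
    "b2m",
    "egr-1",
    "palld",
    "gapdh",
    "bactin",
    "eif4e",
    "ef",
)

IEG_GENES = ("c-fos", "egr-1", "erk-1", "erk-2", "palld", "gapdh")

HPI_GENES = (
    "crf1",
    "crf2",
    "crfr1",
    "crfr2",
    "crh-bp",
    "pomc1",
    "pomc2",
    "gr1",
    "gr2",
    "mr",
)

NEURO_GENES = ("5-ht-r", "serotr", "gabaa", "isopre", "prolr")

#: Gene subset used for the final per-region PCA with group ellipses.
FINAL_PCA_GENES = ("gabaa", "crfr1", "crfr2", "mr", "egr-1", "5-ht-r", "c-fos")

#: Gene-pair ratios tested between groups, (numerator, denominator).
RATIO_PAIRS = (
    ("crf1", "crh-bp"),
    ("crf2", "crh-bp"),
    ("pomc2", "crh-bp"),
    ("pomc1", "crfr2"),
    ("gabaa", "prolr"),
    ("serotr", "gabaa"),
)

ALL_GENES = tuple(
    sorted(set(REFERENCE_CANDIDATES) | set(IEG_GENES) | set(HPI_GENES) | set(NEURO_GENES))
)

REGIONS = ("tel", "hyp", "opt", "rho")

GROUPS = ("control", "stressed")


@dataclass(frozen=True)
class GenePanel:
    """Declared gene panel: reference candidates, targets, ratio pairs."""

    reference_candidates: tuple[str, ...] = REFERENCE_CANDIDATES
    targets: tuple[str, ...] = field(
        default_factory=lambda: tuple(
            sorted(set(IEG_GENES) | set(HPI_GENES) | set(NEURO_GENES))
        )
    )
    ratio_pairs: tuple[tuple[str, str], ...] = RATIO_PAIRS

    def __post_init__(self) -> None:
        if not self.reference_candidates:
            raise ValueError("reference_candidates must be non-empty")
        declared = set(self.reference_candidates) | set(self.targets)
        for num, den in self.ratio_pairs:
            for g in (num, den):
                if g not in declared:
                    raise ValueError(
                        f"ratio pair ({num}, {den}) references undeclared gene {g!r}"
                    )

    @property
    def genes(self) -> tuple[str, ...]:
        """All declared genes, sorted, without duplicates."""
        return tuple(sorted(set(self.reference_candidates) | set(self.targets)))


def default_panel() -> GenePanel:
    """The 26-gene study panel with its 8 reference candidates."""
    return GenePanel()
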