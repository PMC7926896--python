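"""Relative quantification of qPCR data (delta-Ct workflow).

The chain is: collapse technical replicates to a mean Ct per sample and
gene; take delta-Ct against the control-group average for that gene and
region (control mean minus sample, so higher expression gives positive
delta-Ct); convert to relative quantities RQ = efficiency ** delta-Ct;
divide each target's RQ by the sample's normalization factor NF (the
geometric mean of the selected reference genes' RQs); log-transform.
Group summaries (mean, SD, SEM) are computed on the log scale; the
geometric mean on the raw scale is the back-transformed log mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SAMPLE_KEY = ["animal_id", "region", "group"]


@dataclass
class NormalizationSettings:
    efficiency: float = 2.0
    log_base: float = 2.0
    nf_per_group: bool = False  # NF from per-group mean reference RQs instead of per sample
    qc_replicate_sd: float = 0.5  # cycles; replicate scatter above this is flagged


def collapse_replicates(
    ct: pd.DataFrame, qc_replicate_sd: float = 0.5
) -> pd.DataFrame:
    """Mean Ct over non-missing technical replicates per (animal, region, gene).

    Entries with no usable replicate are omitted (and logged).  Replicate
    SD above ``qc_replicate_sd`` cycles sets ``qc_flag``.
    """
    n_all = ct.groupby(SAMPLE_KEY + ["gene"], sort=False).size()
    agg = (
        ct.dropna(subset=["ct"])
        .groupby(SAMPLE_KEY + ["gene"], sort=False)["ct"]
        .agg(mean_ct="mean", replicate_sd="std", n_reps="count")
        .reset_index()
    )
    agg["replicate_sd"] = agg["replicate_sd"].fillna(0.0)
    agg["qc_flag"] = agg["replicate_sd"] > qc_replicate_sd
    n_dropped = len(n_all) - len(agg)
    if n_dropped:
        logger.warning(
            "collapse_replicates: %d (animal, region, gene) entries had no usable replicate and were omitted",
            n_dropped,
        )
    return agg


def delta_ct(mean_ct: pd.DataFrame) -> pd.DataFrame:
    """delta-Ct = control-group average Ct minus sample mean Ct, per gene x region.

    Gene x region cells with no control data are omitted with a warning.
    """
    ctrl = (
        mean_ct[mean_ct["group"] == "control"]
        .groupby(["region", "gene"])["mean_ct"]
        .mean()
        .rename("control_mean_ct")
    )
    out = mean_ct.merge(ctrl, on=["region", "gene"], how="left")
    missing = out["control_mean_ct"].isna()
    if missing.any():
        lost = out.loc[missing, ["region", "gene"]].drop_duplicates()
        logger.warning(
            "delta_ct: no control data for %d gene x region cells; omitted: %s",
            len(lost),
            lost.to_records(index=False),
        )
        out = out[~missing].copy()
    out["delta_ct"] = out["control_mean_ct"] - out["mean_ct"]
    return out


def relative_quantity(delta: pd.DataFrame | np.ndarray, efficiency: float = 2.0):
    """RQ = efficiency ** delta-Ct (expression relative to the control mean)."""
    if not (1.0 < efficiency <= 2.0):
        raise ValueError("efficiency must be in (1, 2]")
    if isinstance(delta, pd.DataFrame):
        out = delta.copy()
        out["rq"] = efficiency ** out["delta_ct"]
        return out
    return efficiency ** np.asarray(delta, dtype=float)


def normalization_factor(
    rq: pd.DataFrame, reference_genes: list[str], per_group: bool = False
) -> pd.DataFrame:
    """Geometric mean of the reference genes' RQs, per sample.

    Samples missing any selected reference gene are dropped for that
    region with a warning.  With ``per_group=True`` the factor is instead
    the geometric mean over each biological group's reference RQs, shared
    by all samples in the group (alternative reading of the method).
    """
    refs = rq[rq["gene"].isin(reference_genes)]
    counts = refs.groupby(SAMPLE_KEY, sort=False)["gene"].nunique()
    complete = counts[counts == len(reference_genes)].index
    incomplete = counts[counts < len(reference_genes)]
    if len(incomplete):
        logger.warning(
            "normalization_factor: %d samples missing a reference gene were dropped",
            len(incomplete),
        )
    refs = refs.set_index(SAMPLE_KEY).loc[complete].reset_index()
    if per_group:
        nf = (
            refs.groupby(["region", "group"], sort=False)["rq"]
            .apply(lambda v: float(np.exp(np.mean(np.log(v)))))
            .rename("nf")
            .reset_index()
        )
        samples = refs[SAMPLE_KEY].drop_duplicates()
        return samples.merge(nf, on=["region", "group"])
    nf = (
        refs.groupby(SAMPLE_KEY, sort=False)["rq"]
        .apply(lambda v: float(np.exp(np.mean(np.log(v)))))
        .rename("nf")
        .reset_index()
    )
    return nf


def normalize(rq: pd.DataFrame, nf: pd.DataFrame, log_base: float = 2.0) -> pd.DataFrame:
    """log_norm = log(rq / nf) in the configured base (default log2)."""
    out = rq.merge(nf, on=SAMPLE_KEY, how="inner")
    if (out["rq"] <= 0).any() or (out["nf"] <= 0).any():
        raise ValueError("relative quantities and normalization factors must be > 0")
    out["log_norm"] = np.log(out["rq"] / out["nf"]) / np.log(log_base)
    return out


def group_summary(norm: pd.DataFrame, log_base: float = 2.0) -> pd.DataFrame:
    """Per (region, gene, group): mean/sd/sem of log_norm and the geometric mean.

    ``geo_mean_raw`` is base ** mean_log, the geometric mean of the
    normalized relative quantities.  Groups of size 1 report the mean only
    (sd/sem are NaN).
    """
    g = norm.groupby(["region", "gene", "group"], sort=False)["log_norm"]
    out = g.agg(mean_log="mean", sd_log="std", n="count").reset_index()
    out["sem_log"] = out["sd_log"] / np.sqrt(out["n"])
    out["geo_mean_raw"] = log_base ** out["mean_log"]
    return out


def normalized_expression(
    ct: pd.DataFrame,
    reference_genes: list[str],
    settings: NormalizationSettings | None = None,
) -> pd.DataFrame:
    """Full chain: replicates -> delta-Ct -> RQ -> NF -> log normalized expression.

    Returns one row per (animal, region, gene) with ``delta_ct, rq, nf,
    log_norm`` columns.
    """
    s = settings or NormalizationSettings()
    mean_ct = collapse_replicates(ct, qc_replicate_sd=s.qc_replicate_sd)
    dct = delta_ct(mean_ct)
    rq = relative_quantity(dct, efficiency=s.efficiency)
    nf = normalization_factor(rq, reference_genes, per_group=s.nf_per_group)
    return normalize(rq, nf, log_base=s.log_base)
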