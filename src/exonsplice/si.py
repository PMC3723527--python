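"""Splicing-index statistics, exon-level tests and the event-calling cascade.

The splicing index (SI) of a probe-set between two conditions is the log2
ratio of its group-mean gene-normalized intensities (NI): with NI kept on
the log2 scale, SI = mean(NI | A) - mean(NI | B).  Positive SI means higher
exon inclusion in condition A ("inclusion" events); negative means
"exclusion".  Differential inclusion is tested per probe-set with a
two-sided t-test (Welch unpaired, or paired by subject) and with a one-way
ANOVA on NI ("MiDAS-style"; for two groups the ANOVA F equals the pooled
t statistic squared).

An event is emitted when all of the following hold (each threshold
configurable): |SI| >= 1 (two-fold change); t-test or ANOVA p < 0.05;
Benjamini-Hochberg FDR q < 0.05; and the gene's own linear fold change
between conditions does not exceed 3 (guarding against transcription-level
changes masquerading as splicing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exprio import ExpressionSet, ExpressionIOError
from .genelevel import GeneExpression, dabg_filter, gene_level, normalized_intensity


class PairingError(ValueError):
    """Raised when a paired test is requested with incomplete subject pairing."""


@dataclass(frozen=True)
class Thresholds:
    """Event-calling thresholds (all configurable).

    ``si_min``: minimum |SI| on the log2 scale (1.0 = two-fold).
    ``p_max``: raw p-value cut for the t-test / ANOVA (either may pass).
    ``fdr_max``: Benjamini-Hochberg q cut on the t-test p-values.
    ``max_gene_fold``: maximum absolute gene-level linear fold change.
    """

    si_min: float = 1.0
    p_max: float = 0.05
    fdr_max: float = 0.05
    max_gene_fold: float = 3.0


@dataclass(frozen=True)
class SplicingEvent:
    """One probe-set's detected inclusion/exclusion change."""

    probeset_id: str
    gene_id: str
    si: float
    direction: str  # "inclusion" | "exclusion"
    t_p: float
    midas_p: float
    fdr_q: float
    gene_fc: float
    method: str = "si"


EVENT_COLUMNS = ["probeset_id", "gene_id", "si", "direction",
                 "t_p", "midas_p", "fdr_q", "gene_fc", "method"]


def _group_matrix(ni: pd.DataFrame, design: pd.DataFrame, cond: str) -> np.ndarray:
    samples = design.index[design["group"] == cond]
    if not len(samples):
        raise ExpressionIOError(f"condition {cond!r} absent from the design")
    return ni[list(samples)].to_numpy()


def splicing_index(
    ni: pd.DataFrame, design: pd.DataFrame, cond_a: str, cond_b: str
) -> pd.Series:
    """SI per probe-set: mean log2 NI in ``cond_a`` minus mean in ``cond_b``."""
    a = _group_matrix(ni, design, cond_a)
    b = _group_matrix(ni, design, cond_b)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ExpressionIOError("each condition needs >= 2 samples for SI analysis")
    return pd.Series(a.mean(axis=1) - b.mean(axis=1), index=ni.index, name="si")


def _paired_columns(
    design: pd.DataFrame, cond_a: str, cond_b: str
) -> tuple[list[str], list[str]]:
    da = design[design["group"] == cond_a]
    db = design[design["group"] == cond_b]
    db_by_subj = {sid: samp for samp, sid in db["subject"].dropna().items()}
    cols_a, cols_b, unpaired = [], [], []
    for samp, row in da.iterrows():
        sid = row["subject"]
        if pd.isna(sid) or sid not in db_by_subj:
            unpaired.append(samp)
        else:
            cols_a.append(samp)
            cols_b.append(db_by_subj[sid])
    if unpaired:
        raise PairingError(
            f"paired test requested but samples lack a {cond_b!r} mate: {unpaired}")
    return cols_a, cols_b


def exon_test(
    ni: pd.DataFrame,
    design: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    paired: bool = False,
) -> pd.DataFrame:
    """Two-sided t-test and one-way ANOVA p-values on NI, per probe-set.

    Unpaired comparisons use the Welch (unequal-variance) t-test; paired
    comparisons the paired t-test matched by subject id.  The ANOVA column
    (``midas_p``) is always the unpaired one-way group ANOVA.  Degenerate
    rows (zero variance, or fewer than two usable values) get p = 1 so they
    can never pass the filter cascade.
    """
    a = _group_matrix(ni, design, cond_a)
    b = _group_matrix(ni, design, cond_b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if paired:
            cols_a, cols_b = _paired_columns(design, cond_a, cond_b)
            diffs = ni[cols_a].to_numpy() - ni[cols_b].to_numpy()
            t_p = stats.ttest_rel(ni[cols_a].to_numpy(), ni[cols_b].to_numpy(),
                                  axis=1).pvalue
            degen_t = diffs.std(axis=1) < _DEGENERATE_TOL
            sep_t = np.abs(diffs.mean(axis=1)) > _DEGENERATE_TOL
        else:
            t_p = stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
            degen_t = (a.std(axis=1) < _DEGENERATE_TOL) & (b.std(axis=1) < _DEGENERATE_TOL)
            sep_t = np.abs(a.mean(axis=1) - b.mean(axis=1)) > _DEGENERATE_TOL
        midas_p = stats.f_oneway(a, b, axis=1).pvalue
    degen_f = (a.std(axis=1) < _DEGENERATE_TOL) & (b.std(axis=1) < _DEGENERATE_TOL)
    sep_f = np.abs(a.mean(axis=1) - b.mean(axis=1)) > _DEGENERATE_TOL
    t_p = _resolve_degenerate(t_p, degen_t, sep_t)
    midas_p = _resolve_degenerate(midas_p, degen_f, sep_f)
    return pd.DataFrame({"t_p": t_p, "midas_p": midas_p}, index=ni.index)


_DEGENERATE_TOL = 1e-8


def _resolve_degenerate(p: np.ndarray, degenerate: np.ndarray,
                        separated: np.ndarray) -> np.ndarray:
    """Zero-variance rows: p = 0 when the group means genuinely differ
    (the noise-free planted-event limit), p = 1 when they are numerically
    identical — so float dust can never pass the filters."""
    p = np.where(degenerate, np.where(separated, 0.0, 1.0), p)
    return np.where(np.isfinite(p), p, 1.0)


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone in rank)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if not np.all(np.isfinite(p)):
        raise ValueError("FDR adjustment requires finite p-values")
    return multipletests(p, method="fdr_bh")[1]


def gene_fold_change(
    ge: GeneExpression, design: pd.DataFrame, cond_a: str, cond_b: str
) -> pd.Series:
    """Linear gene-level fold change A vs B (2 ** mean log2 difference)."""
    a = _group_matrix(ge.values, design, cond_a)
    b = _group_matrix(ge.values, design, cond_b)
    return pd.Series(2.0 ** (a.mean(axis=1) - b.mean(axis=1)),
                     index=ge.values.index, name="gene_fc")


def call_events(
    si: pd.Series,
    t_p: pd.Series,
    midas_p: pd.Series,
    fdr_q: pd.Series,
    gene_fc: pd.Series,
    thresholds: Thresholds | None = None,
    gene_ids: pd.Series | None = None,
    method: str = "si",
) -> pd.DataFrame:
    """Apply the filter cascade; return emitted events as a DataFrame.

    All inputs are aligned by probe-set id (``gene_fc`` here is already the
    per-probe-set linear fold change of the owning gene).
    """
    th = thresholds or Thresholds()
    abs_fc = np.maximum(gene_fc, 1.0 / gene_fc)
    mask = (
        (si.abs() >= th.si_min)
        & ((t_p < th.p_max) | (midas_p < th.p_max))
        & (fdr_q < th.fdr_max)
        & (abs_fc <= th.max_gene_fold)
    )
    idx = si.index[mask]
    out = pd.DataFrame({
        "probeset_id": idx,
        "gene_id": (gene_ids.loc[idx].to_numpy() if gene_ids is not None
                    else [""] * len(idx)),
        "si": si.loc[idx].to_numpy(),
        "direction": np.where(si.loc[idx] > 0, "inclusion", "exclusion"),
        "t_p": t_p.loc[idx].to_numpy(),
        "midas_p": midas_p.loc[idx].to_numpy(),
        "fdr_q": fdr_q.loc[idx].to_numpy(),
        "gene_fc": gene_fc.loc[idx].to_numpy(),
        "method": method,
    }).reset_index(drop=True)
    return out[EVENT_COLUMNS]


def events_from_frame(df: pd.DataFrame) -> list[SplicingEvent]:
    return [SplicingEvent(**{k: row[k] for k in EVENT_COLUMNS})
            for _, row in df.iterrows()]


def si_statistics(
    es: ExpressionSet,
    cond_a: str,
    cond_b: str,
    paired: bool = False,
) -> pd.DataFrame:
    """Full per-probe-set statistics table (si, t_p, midas_p, fdr_q, gene_fc).

    Expects an already detection-filtered ExpressionSet; computes gene-level
    estimates, NI, SI, tests and the BH adjustment (applied to the t-test
    p-values over all tested probe-sets of this comparison).
    """
    ge = gene_level(es)
    ni = normalized_intensity(es, ge)
    si = splicing_index(ni, es.design, cond_a, cond_b)
    tests = exon_test(ni, es.design, cond_a, cond_b, paired=paired)
    q = pd.Series(fdr_bh(tests["t_p"].to_numpy()), index=ni.index, name="fdr_q")
    gfc = gene_fold_change(ge, es.design, cond_a, cond_b)
    genes = es.gene_of().loc[ni.index]
    stats_df = pd.DataFrame({
        "gene_id": genes,
        "si": si,
        "t_p": tests["t_p"],
        "midas_p": tests["midas_p"],
        "fdr_q": q,
        "gene_fc": gfc.loc[genes].to_numpy(),
    })
    return stats_df


def detect_events(
    es: ExpressionSet,
    cond_a: str,
    cond_b: str,
    paired: bool = False,
    thresholds: Thresholds | None = None,
    dabg_alpha: float = 0.05,
    dabg_min_fraction: float = 1.0,
    apply_dabg: bool = True,
) -> pd.DataFrame:
    """Convenience: DABG filter -> gene level -> NI -> SI cascade -> events."""
    if apply_dabg and es.dabg is not None:
        es = dabg_filter(es, alpha=dabg_alpha, min_fraction=dabg_min_fraction)
    st = si_statistics(es, cond_a, cond_b, paired=paired)
    return call_events(st["si"], st["t_p"], st["midas_p"], st["fdr_q"],
                       st["gene_fc"], thresholds, gene_ids=st["gene_id"],
                       method="si")
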