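"""FIRMA: exon deviation scores from a robust per-gene additive probe model.

Where the splicing index normalizes each probe-set by an explicit gene-level
estimate, FIRMA fits the RMA-style additive model

    y[probe, sample] = mu + probe_effect + chip_effect + residual

to all probes of a gene (log2 scale) by Tukey median polish, and scores each
probe-set in each sample by the median of its probes' residuals divided by a
robust scale (1.4826 x the median absolute deviation of all residuals of the
gene, floored at 1e-8).  An exon that is differentially included leaves the
additive model unexplained in the affected samples, producing scores far
from zero there; data generated exactly by the additive model yield all-zero
scores.

Testing and filtering reuse the splicing-index contract, with the effect
size taken as the difference of group-mean FIRMA scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exprio import ExpressionSet
from .genelevel import GeneExpression, gene_level
from .si import Thresholds, call_events, exon_test, fdr_bh, gene_fold_change, splicing_index

RESID_SCALE_FLOOR = 1e-8
MAD_TO_SD = 1.4826      # consistency factor for Gaussian data
_NUMERIC_ZERO = 1e-10   # residual magnitudes below this are float dust


def median_polish(
    x: np.ndarray, max_iter: int = 20, tol: float = 1e-6
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish of a 2-D array.

    Each sweep subtracts row medians of the residual (accumulated into row
    effects), re-centres the row effects by their median (moved into the
    overall term), then does the same for columns.  Stops when the largest
    median removed in a sweep falls below ``tol`` or after ``max_iter``
    sweeps.  Returns ``(overall, row_effects, col_effects, residuals)``;
    row and column effects each have median zero.
    """
    resid = np.array(x, dtype=float, copy=True)
    if resid.ndim != 2:
        raise ValueError("median_polish expects a 2-D array")
    nr, nc = resid.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    for _ in range(max_iter):
        rmed = np.median(resid, axis=1)
        resid -= rmed[:, None]
        row += rmed
        m = np.median(row)
        row -= m
        overall += m
        cmed = np.median(resid, axis=0)
        resid -= cmed[None, :]
        col += cmed
        m = np.median(col)
        col -= m
        overall += m
        if max(np.abs(rmed).max(initial=0.0), np.abs(cmed).max(initial=0.0)) < tol:
            break
    return overall, row, col, resid


def fit_additive(probe_matrix: pd.DataFrame) -> tuple[pd.Series, pd.Series, pd.DataFrame]:
    """Fit the additive probe model for one gene's probe x sample log2 matrix.

    Returns ``(chip_effects, probe_effects, residuals)`` where chip effects
    absorb the overall term (they estimate per-sample gene expression) and
    probe effects have median zero.  An all-constant matrix yields zero
    residuals; that is degenerate but valid.
    """
    overall, row, col, resid = median_polish(probe_matrix.to_numpy())
    chip = pd.Series(overall + col, index=probe_matrix.columns, name="chip")
    probe = pd.Series(row, index=probe_matrix.index, name="probe")
    return chip, probe, pd.DataFrame(resid, index=probe_matrix.index,
                                     columns=probe_matrix.columns)


def firma_scores(residuals: pd.DataFrame, probe_to_ps: pd.Series) -> pd.DataFrame:
    """Probe-set x sample FIRMA scores from one gene's residual matrix.

    ``probe_to_ps`` maps probe ids (the residual rows) to probe-set ids.
    Scale: MAD of all the gene's residuals x 1.4826, floored at 1e-8.
    Probe-sets with zero probes in the matrix are simply absent.
    """
    r = residuals.to_numpy()
    mad = np.median(np.abs(r - np.median(r)))
    scale = max(MAD_TO_SD * mad, RESID_SCALE_FLOOR)
    groups = probe_to_ps.loc[residuals.index]
    rows = {}
    for ps, probes in groups.groupby(groups).groups.items():
        med = np.median(residuals.loc[probes].to_numpy(), axis=0)
        med[np.abs(med) < _NUMERIC_ZERO] = 0.0  # exact-additive-model limit
        rows[ps] = med / scale
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=residuals.columns).sort_index()


def compute_firma(
    probes: pd.DataFrame,
    probe_to_ps: pd.Series,
    probeset_map: pd.DataFrame,
) -> pd.DataFrame:
    """FIRMA scores for all genes from a probe-level log2 matrix.

    ``probes``: probe x sample log2 intensities; ``probe_to_ps``: probe id ->
    probe-set id; ``probeset_map``: probe-set -> gene map (as in
    :class:`~exonsplice.exprio.ExpressionSet`).  When no probe-level data
    exist, callers may pass the probe-set matrix itself with an identity
    ``probe_to_ps``: FIRMA then degrades to a single-probe-per-set fit.
    """
    ps_of_probe = probe_to_ps.loc[probes.index]
    gene_of_probe = probeset_map.loc[ps_of_probe, "gene_id"]
    gene_of_probe.index = probes.index
    blocks = []
    for gid, probe_idx in gene_of_probe.groupby(gene_of_probe).groups.items():
        sub = probes.loc[probe_idx]
        _, _, resid = fit_additive(sub)
        blocks.append(firma_scores(resid, ps_of_probe))
    scores = pd.concat(blocks).sort_index()
    return scores


def firma_test(
    scores: pd.DataFrame,
    es: ExpressionSet,
    cond_a: str,
    cond_b: str,
    paired: bool = False,
    thresholds: Thresholds | None = None,
    ge: GeneExpression | None = None,
) -> pd.DataFrame:
    """Test FIRMA scores between conditions and apply the event cascade.

    Effect size is the difference of group-mean scores (reported in the
    ``si`` column of the events table, method="firma"); the t-test/ANOVA,
    BH adjustment and gene-level fold-change gate mirror the SI cascade.
    """
    design = es.design
    effect = splicing_index(scores, design, cond_a, cond_b)
    tests = exon_test(scores, design, cond_a, cond_b, paired=paired)
    q = pd.Series(fdr_bh(tests["t_p"].to_numpy()), index=scores.index, name="fdr_q")
    if ge is None:
        ge = gene_level(es)
    gfc_gene = gene_fold_change(ge, design, cond_a, cond_b)
    genes = es.probeset_map.loc[scores.index, "gene_id"]
    gfc = pd.Series(gfc_gene.reindex(genes).fillna(1.0).to_numpy(),
                    index=scores.index)
    return call_events(effect, tests["t_p"], tests["midas_p"], q, gfc,
                       thresholds, gene_ids=genes, method="firma")
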