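"""Transcriptomic rescue classification across three isogenic contrasts.

Downstream of differential expression (DE tables with per-gene log2 fold
change and adjusted p are consumed, not computed): TPM normalization, the
bimodal expressed-gene cutoff, up/down DE calls in the disease-vs-control
contrast, and the rescue rule across the three contrasts
(control vs CUG, CUG vs CCG, control vs CCG). A DE gene counts as rescued
when it changes significantly upon CUG->CCG editing, or when the edited
line is statistically indistinguishable from control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CutoffResult",
    "RescueSummary",
    "tpm_normalize",
    "expressed_gene_cutoff",
    "adjust_pvalues",
    "call_de",
    "classify_rescue",
    "rescue_summary",
]

REQUIRED_COLUMNS = ("log2fc", "padj")


def _check_contrast(df: pd.DataFrame, name: str) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"contrast table {name!r} lacks column {col!r}")
    if not np.all(np.isfinite(df["log2fc"].to_numpy(float))):
        raise ValueError(f"contrast table {name!r} has non-finite log2fc")
    return df


def tpm_normalize(counts: pd.DataFrame, lengths_kb: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million normalization of a gene x sample count matrix.

    Per sample: rate_g = count_g / length_g (kb); TPM_g = 1e6 * rate_g /
    sum(rates). Every output column sums to 1e6.
    """
    lengths_kb = lengths_kb.reindex(counts.index)
    if lengths_kb.isna().any():
        raise ValueError("every gene needs a length")
    if (lengths_kb <= 0).any():
        raise ValueError("gene lengths must be > 0")
    rates = counts.div(lengths_kb, axis=0)
    totals = rates.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"all-zero sample(s): {bad}")
    return rates.div(totals, axis=1) * 1e6


@dataclass
class CutoffResult:
    cutoff_tpm: float
    expressed: pd.Index
    fallback: bool
    pseudocount: float


def expressed_gene_cutoff(
    tpm: pd.DataFrame,
    pseudocount: float = 0.01,
    grid_points: int = 512,
) -> CutoffResult:
    """Expressed-gene cutoff from the bimodal distribution of expression.

    A Gaussian KDE (Scott's-rule bandwidth) of mean log10(TPM + pseudocount)
    is scanned for modes; the cutoff is the density minimum between the two
    largest modes, and genes with mean TPM above it are "expressed". When no
    bimodality is detected the cutoff falls back to 1 TPM with a warning.
    """
    if tpm.shape[0] < 100:
        raise ValueError("need at least 100 genes to estimate the cutoff")
    x = np.log10(tpm.mean(axis=1).to_numpy(float) + pseudocount)
    kde = gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), grid_points)
    dens = kde(grid)
    interior = np.arange(1, grid_points - 1)
    peaks = interior[(dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])]
    fallback = False
    if len(peaks) < 2:
        fallback = True
        cutoff = 1.0
        warnings.warn(
            "no bimodality detected in expression density; "
            "falling back to a cutoff of 1 TPM",
            UserWarning,
            stacklevel=2,
        )
    else:
        top2 = peaks[np.argsort(dens[peaks])][-2:]
        lo, hi = sorted(top2)
        valley = lo + int(np.argmin(dens[lo : hi + 1]))
        cutoff = float(10 ** grid[valley] - pseudocount)
    expressed = tpm.index[tpm.mean(axis=1) > cutoff]
    return CutoffResult(cutoff, expressed, fallback, pseudocount)


def adjust_pvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjustment for raw p-values (NaN passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def call_de(
    contrast: pd.DataFrame, lfc_min: float = 0.5, padj_max: float = 0.05
) -> pd.Series:
    """Per-gene DE status: 'up', 'down' or 'not_de'.

    Inequalities are strict (log2fc > lfc_min, padj < padj_max); boundary
    values and missing padj are not significant.
    """
    if lfc_min <= 0 or padj_max <= 0:
        raise ValueError("thresholds must be positive")
    _check_contrast(contrast, "contrast")
    lfc = contrast["log2fc"].to_numpy(float)
    padj = contrast["padj"].to_numpy(float)
    sig = np.isfinite(padj) & (padj < padj_max)
    status = np.where(
        sig & (lfc > lfc_min), "up", np.where(sig & (lfc < -lfc_min), "down", "not_de")
    )
    return pd.Series(status, index=contrast.index, name="de_status")


def classify_rescue(
    ctrl_vs_cug: pd.DataFrame,
    cug_vs_ccg: pd.DataFrame,
    ctrl_vs_ccg: pd.DataFrame,
    lfc_min: float = 0.5,
    padj_max: float = 0.05,
    require_opposite_direction: bool = False,
) -> pd.DataFrame:
    """Classify every DE gene of the disease contrast as rescued or not.

    A gene that is DE in control-vs-CUG is *rescued* when

    1. ``|log2fc| > lfc_min`` and ``padj < padj_max`` in CUG-vs-CCG
       (the editing changed its expression), or
    2. ``padj > padj_max`` in control-vs-CCG (the edited line is
       indistinguishable from control).

    Clause 1 is checked first and recorded in ``criterion_used``. With
    ``require_opposite_direction`` the clause-1 change must additionally
    oppose the sign of the disease-contrast change. Missing padj counts as
    not significant in clause 1 and as not satisfying clause 2 (the gene is
    flagged). Genes absent from any table are flagged and excluded from
    summaries. Non-DE genes are 'not_applicable'.
    """
    a = _check_contrast(ctrl_vs_cug, "ctrl_vs_cug")
    b = _check_contrast(cug_vs_ccg, "cug_vs_ccg")
    c = _check_contrast(ctrl_vs_ccg, "ctrl_vs_ccg")
    genes = a.index
    de = call_de(a, lfc_min, padj_max)

    b = b.reindex(genes)
    c = c.reindex(genes)
    missing = np.asarray(
        ~genes.isin(cug_vs_ccg.index) | ~genes.isin(ctrl_vs_ccg.index)
    )

    b_lfc = b["log2fc"].to_numpy(float)
    b_padj = b["padj"].to_numpy(float)
    c_padj = c["padj"].to_numpy(float)
    a_lfc = a["log2fc"].to_numpy(float)

    clause1 = (
        np.isfinite(b_padj)
        & (b_padj < padj_max)
        & (np.abs(b_lfc) > lfc_min)
    )
    if require_opposite_direction:
        clause1 &= np.sign(b_lfc) == -np.sign(a_lfc)
    clause2 = np.isfinite(c_padj) & (c_padj > padj_max)
    padj_na_flag = ~np.isfinite(c_padj)

    is_de = de.isin(["up", "down"]).to_numpy()
    evaluable = is_de & ~missing
    rescued = evaluable & (clause1 | clause2)

    status = np.where(is_de, "not_rescued", "not_applicable")
    status = np.where(rescued, "rescued", status)
    criterion = np.full(len(genes), "none", dtype=object)
    criterion[rescued & clause1] = "cug_vs_ccg_change"
    criterion[rescued & ~clause1 & clause2] = "ccg_equals_control"

    return pd.DataFrame(
        {
            "de_status": de.to_numpy(),
            "rescue_status": status,
            "criterion_used": criterion,
            "flagged_missing": missing,
            "flagged_padj_na": padj_na_flag & is_de,
        },
        index=genes,
    )


@dataclass
class RescueSummary:
    n_up: int
    n_down: int
    n_rescued: int
    pct_rescued: float  # NaN when no DE genes
    defined: bool
    n_flagged: int = 0


def rescue_summary(calls: pd.DataFrame) -> RescueSummary:
    """Counts of up/down/rescued genes and the rescued percentage.

    Genes flagged as missing from a contrast table are excluded. The
    percentage is undefined (NaN, ``defined=False``) with zero DE genes.
    """
    if calls.empty:
        raise ValueError("calls table is empty")
    ok = ~calls["flagged_missing"]
    sub = calls[ok]
    n_up = int((sub["de_status"] == "up").sum())
    n_down = int((sub["de_status"] == "down").sum())
    n_rescued = int((sub["rescue_status"] == "rescued").sum())
    n_de = n_up + n_down
    if n_de == 0:
        warnings.warn("no DE genes: rescued percentage undefined", UserWarning,
                      stacklevel=2)
        return RescueSummary(0, 0, 0, float("nan"), False,
                             int((~ok).sum()))
    return RescueSummary(
        n_up, n_down, n_rescued, 100.0 * n_rescued / n_de, True, int((~ok).sum())
    )
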