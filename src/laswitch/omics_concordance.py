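"""Decision rules for two-condition multi-omics comparison.

Differential expression calling uses Benjamini–Hochberg adjusted
p-values (< 0.05) combined with an absolute log2 fold-change threshold
(default 1.5).  Spectral-count proteomics uses the replicate-averaged
fold-change rule (significant beyond twofold in either direction).
Transcript and protein calls are cross-tabulated into concordance
categories, and metabolite changes are summarised as log-ratios with
Welch t-tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DeRecord",
    "ConcordanceCell",
    "bh_adjust",
    "call_deg",
    "spectral_fold_changes",
    "concordance_matrix",
    "metabolite_log_ratios",
    "rank_correlation",
    "replicate_correlation",
]


@dataclass
class DeRecord:
    feature_id: str
    log2fc: float
    pvalue: float
    padj: float | None = None
    call: str = "ns"


@dataclass(frozen=True)
class ConcordanceCell:
    feature_id: str
    rna_call: str
    protein_call: str
    category: str


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order.

    Sort ascending, scale p(i) by m/i, enforce monotonicity from the
    largest rank downward, cap at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def call_deg(records: pd.DataFrame, lfc_threshold: float = 1.5,
             alpha: float = 0.05, adjust: bool = True) -> pd.DataFrame:
    """Call features up/down/ns from a log2fc + p-value table.

    ``records`` needs columns ``feature_id``, ``log2fc`` and ``pvalue``
    (or a precomputed ``padj`` when ``adjust=False``).  A feature is
    ``up`` if log2fc ≥ lfc_threshold and padj < alpha, ``down`` if
    log2fc ≤ −lfc_threshold and padj < alpha, else ``ns``.
    """
    df = records.copy()
    if adjust:
        if "pvalue" not in df.columns:
            raise ValueError("records need a 'pvalue' column")
        df["padj"] = bh_adjust(df["pvalue"].to_numpy())
    elif "padj" not in df.columns or df["padj"].isna().any():
        raise ValueError("padj missing; run with adjust=True or fill it")
    sig = df["padj"].to_numpy() < alpha
    lfc = df["log2fc"].to_numpy()
    call = np.where(sig & (lfc >= lfc_threshold), "up",
                    np.where(sig & (lfc <= -lfc_threshold), "down", "ns"))
    df["call"] = call
    return df


def spectral_fold_changes(table: pd.DataFrame, pseudocount: float = 1.0,
                          fc_threshold: float = 2.0) -> pd.DataFrame:
    """Replicate-averaged spectral-count fold-changes with the FC>2 rule.

    ``table`` is proteins × replicates with ``ca_*`` / ``la_*`` columns.
    FC = (mean_La + pseudocount) / (mean_Ca + pseudocount); significant
    if FC > fc_threshold or FC < 1/fc_threshold.
    """
    ca_cols = [c for c in table.columns if c.startswith("ca_")]
    la_cols = [c for c in table.columns if c.startswith("la_")]
    if not ca_cols or not la_cols:
        raise ValueError("spectral table must have ca_* and la_* columns")
    if table[ca_cols + la_cols].isna().any().any():
        raise ValueError("protein absent from one condition (NaN counts)")
    mean_ca = table[ca_cols].mean(axis=1)
    mean_la = table[la_cols].mean(axis=1)
    fc = (mean_la + pseudocount) / (mean_ca + pseudocount)
    call = np.where(fc > fc_threshold, "up",
                    np.where(fc < 1.0 / fc_threshold, "down", "ns"))
    return pd.DataFrame({
        "protein_id": table.index,
        "mean_ca": mean_ca.to_numpy(),
        "mean_la": mean_la.to_numpy(),
        "fold_change": fc.to_numpy(),
        "significant": call != "ns",
        "call": call,
    }).reset_index(drop=True)


_CATEGORIES = ("concordant_up", "concordant_down", "discordant",
               "protein_only", "rna_only", "ns")


def _categorise(rna: str, protein: str) -> str:
    if rna == "ns" and protein == "ns":
        return "ns"
    if rna == "ns":
        return "protein_only"
    if protein == "ns":
        return "rna_only"
    if rna == protein:
        return f"concordant_{rna}"
    return "discordant"


def concordance_matrix(rna_calls: pd.DataFrame, protein_calls: pd.DataFrame
                       ) -> tuple[list[ConcordanceCell], dict[str, int]]:
    """Cross-tabulate transcript and protein calls per feature.

    Inputs are frames with ``feature_id``/``protein_id`` and ``call``
    columns; features absent from one table count as ``ns`` there
    (outer join).  Returns the per-feature cells and category counts.
    """
    rna = rna_calls.set_index(rna_calls.columns[0])["call"]
    prot = protein_calls.set_index(protein_calls.columns[0])["call"]
    features = rna.index.union(prot.index)
    cells = [
        ConcordanceCell(str(f), rna.get(f, "ns"), prot.get(f, "ns"),
                        _categorise(rna.get(f, "ns"), prot.get(f, "ns")))
        for f in features
    ]
    counts = {cat: 0 for cat in _CATEGORIES}
    for cell in cells:
        counts[cell.category] += 1
    return cells, counts


def metabolite_log_ratios(abundances: pd.DataFrame) -> pd.DataFrame:
    """Per-metabolite log2(La/Ca) with a Welch t-test on log abundances.

    Zeros are replaced by half the smallest positive value in the table;
    all-zero metabolites are dropped with a warning.
    """
    ca_cols = [c for c in abundances.columns if c.startswith("ca_")]
    la_cols = [c for c in abundances.columns if c.startswith("la_")]
    if not ca_cols or not la_cols:
        raise ValueError("abundance table must have ca_* and la_* columns")
    values = abundances[ca_cols + la_cols]
    all_zero = (values <= 0).all(axis=1)
    if all_zero.any():
        warnings.warn(f"excluding all-zero metabolites: "
                      f"{list(abundances.index[all_zero])}", stacklevel=2)
        abundances = abundances[~all_zero]
    mat = abundances[ca_cols + la_cols].to_numpy(float)
    positive_min = mat[mat > 0].min()
    mat = np.where(mat <= 0, positive_min / 2.0, mat)
    ca = mat[:, :len(ca_cols)]
    la = mat[:, len(ca_cols):]
    log2fc = np.log2(la.mean(axis=1) / ca.mean(axis=1))
    if len(ca_cols) >= 2 and len(la_cols) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            _, pvals = stats.ttest_ind(np.log(la), np.log(ca), axis=1,
                                       equal_var=False)
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
    else:
        pvals = np.full(len(log2fc), np.nan)
    return pd.DataFrame({
        "metabolite": abundances.index,
        "log2fc": log2fc,
        "pvalue": pvals,
    }).reset_index(drop=True)


def _rankdata(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        return float("nan")
    return float(rx @ ry / denom)


def rank_correlation(predicted, observed,
                     exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman rank correlation with an exact permutation p for small n.

    Average ranks for ties; for n ≤ ``exact_max_n`` the two-sided p-value
    is the exact fraction of permutations with |rho| at least as extreme,
    otherwise the usual t-approximation is used.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx, ry = _rankdata(x), _rankdata(y)
    rho = _spearman_rho(rx, ry)
    if math.isnan(rho):
        return rho, float("nan")
    if n <= exact_max_n:
        count = 0
        total = 0
        for perm in permutations(ry):
            r = _spearman_rho(rx, np.asarray(perm))
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = 2.0 * stats.t.sf(abs(t), n - 2)
    return rho, float(min(p, 1.0))


def replicate_correlation(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r on log(count+1) within each condition.

    Constant replicate vectors yield an undefined correlation, flagged
    as NaN in the result.
    """
    groups: dict[str, list[str]] = {}
    for col in counts.columns:
        cond = col.split("_")[0]
        groups.setdefault(cond, []).append(col)
    rows = []
    for cond, cols in groups.items():
        if len(cols) < 2:
            continue
        logged = np.log(counts[cols].to_numpy(float) + 1.0)
        for (i, a), (j, b) in combinations(enumerate(cols), 2):
            xa, xb = logged[:, i], logged[:, j]
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                r = float("nan")
            else:
                r = float(np.corrcoef(xa, xb)[0, 1])
            rows.append({"condition": cond, "rep_a": a, "rep_b": b,
                         "pearson_r": r})
    if not rows:
        raise ValueError("need at least 2 replicates in some condition")
    return pd.DataFrame(rows)
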