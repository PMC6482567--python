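"""qPCR relative quantification (2^-ddCt) and tissue-expression summaries.

Fold changes follow the standard comparative-Ct model with amplification
efficiency fixed at 2: technical replicates are averaged first, dCt is
taken against the reference gene within each biological replicate, ddCt
against the calibrator condition, and the per-condition mean and standard
error are computed across biological replicates only.  Tissue specificity
is quantified with the tau index on log-transformed values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

CT_COLUMNS = ["gene", "condition", "bio_rep", "tech_rep", "ct"]


class ExpressionError(ValueError):
    pass


def _validate_ct(ct: pd.DataFrame, reference: str, calibrator: str) -> None:
    missing = set(CT_COLUMNS) - set(ct.columns)
    if missing:
        raise ExpressionError(f"Ct table missing columns {sorted(missing)}")
    if (ct["ct"] <= 0).any():
        raise ExpressionError("Ct values must be positive")
    conditions = set(ct["condition"])
    ref_conditions = set(ct.loc[ct["gene"] == reference, "condition"])
    absent = sorted(conditions - ref_conditions)
    if absent:
        raise ExpressionError(
            f"reference {reference!r} has no Ct in condition(s) {absent}")
    for gene, sub in ct.groupby("gene"):
        if calibrator not in set(sub["condition"]):
            raise ExpressionError(
                f"calibrator {calibrator!r} missing for gene {gene!r}")


def ddct(ct: pd.DataFrame, reference: str, calibrator: str) -> pd.DataFrame:
    """2^-ddCt fold changes with SE across biological replicates.

    Returns one row per (gene, condition) with columns ``fold`` and ``se``;
    the calibrator condition has fold exactly 1 for every gene.
    """
    _validate_ct(ct, reference, calibrator)
    # technical replicates averaged within (gene, condition, bio_rep)
    mean_ct = (ct.groupby(["gene", "condition", "bio_rep"])["ct"]
               .mean().reset_index())
    ref = (mean_ct[mean_ct["gene"] == reference]
           .rename(columns={"ct": "ct_ref"})
           .drop(columns="gene"))
    tgt = mean_ct[mean_ct["gene"] != reference]
    merged = tgt.merge(ref, on=["condition", "bio_rep"], how="left")
    if merged["ct_ref"].isna().any():
        bad = merged[merged["ct_ref"].isna()]["condition"].unique()
        raise ExpressionError(f"reference Ct missing in {sorted(bad)}")
    merged["dct"] = merged["ct"] - merged["ct_ref"]
    cal = (merged[merged["condition"] == calibrator]
           [["gene", "bio_rep", "dct"]]
           .rename(columns={"dct": "dct_cal"}))
    merged = merged.merge(cal, on=["gene", "bio_rep"], how="left")
    if merged["dct_cal"].isna().any():
        raise ExpressionError("calibrator dCt missing for some bio replicate")
    merged["fold_rep"] = 2.0 ** -(merged["dct"] - merged["dct_cal"])
    out = (merged.groupby(["gene", "condition"])["fold_rep"]
           .agg(fold="mean", se=lambda x: x.std(ddof=1) / np.sqrt(len(x))
                if len(x) > 1 else 0.0)
           .reset_index())
    return out


# ---------------------------------------------------------------------------
# Tissue matrix

def tissue_profile(matrix: pd.DataFrame, log_base: float = 2.0,
                   pseudo: float = 1.0) -> tuple[pd.DataFrame, list[str]]:
    """Log-transformed, row z-scored matrix plus a clustered gene ordering.

    Genes are ordered by average-linkage hierarchical clustering on
    Euclidean row distances (heatmap leaf order, deterministic).  Constant
    rows z-score to zeros rather than NaN.
    """
    if matrix.isna().any().any() or (matrix < 0).any().any():
        raise ExpressionError("matrix must be finite and non-negative")
    logm = np.log(matrix + pseudo) / np.log(log_base)
    mu = logm.mean(axis=1)
    sd = logm.std(axis=1, ddof=0)
    z = logm.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    if len(z) > 1:
        link = hierarchy.linkage(pdist(z.values), method="average")
        order = hierarchy.leaves_list(
            hierarchy.optimal_leaf_ordering(link, pdist(z.values)))
        genes = [matrix.index[i] for i in order]
    else:
        genes = list(matrix.index)
    return z, genes


def tissue_specificity(matrix: pd.DataFrame, log_base: float = 2.0,
                       pseudo: float = 1.0) -> pd.DataFrame:
    """Per-gene tau index and dominant tissue.

    tau = sum(1 - x_i/x_max) / (n-1) on log-transformed values: 0 for a
    uniform profile, 1 for single-tissue expression.  All-zero genes get
    tau = NaN with a flag; argmax ties break by column order and are
    flagged.
    """
    if matrix.shape[1] < 2:
        raise ExpressionError("need at least 2 tissues")
    logm = np.log(matrix + pseudo) / np.log(log_base)
    rows = []
    for gene, x in logm.iterrows():
        xmax = x.max()
        if xmax <= 0:
            rows.append((gene, np.nan, "", "all_zero"))
            continue
        tau = float((1.0 - x / xmax).sum() / (len(x) - 1))
        top = x.idxmax()
        tie = (x == xmax).sum() > 1
        rows.append((gene, tau, top, "tie" if tie else ""))
    return pd.DataFrame(rows, columns=["gene", "tau", "top_tissue", "flag"]
                        ).set_index("gene")
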