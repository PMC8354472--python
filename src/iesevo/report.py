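"""Descriptive statistics over an IES catalog.

Proportion contrasts (weak IESs by compartment or age class, pathway-
sensitive fractions, densities by expression decile) are tested with
chi-squared contingency tests without continuity correction; small
expected cell counts trigger a warning flag rather than suppressing the
test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency


def proportions_report(frame: pd.DataFrame, group_col: str,
                       outcome_col: str) -> dict:
    """Per-group outcome proportions with a chi-squared test.

    ``frame`` must have one row per record; ``outcome_col`` is boolean
    (records with a missing outcome are excluded from the proportions).
    """
    sub = frame.dropna(subset=[outcome_col, group_col])
    table = pd.crosstab(sub[group_col], sub[outcome_col].astype(bool))
    table = table.reindex(columns=[False, True], fill_value=0)
    props = (table[True] / table.sum(axis=1)).rename("proportion")
    if table.shape[0] < 2 or (table.sum(axis=0) == 0).any() \
            or (table.sum(axis=1) == 0).any():
        return {"table": table, "proportions": props, "chi2": np.nan,
                "p_value": np.nan, "small_sample": True}
    chi2, p, dof, expected = chi2_contingency(table.to_numpy(),
                                              correction=False)
    small = bool((expected < 5).any())
    if small:
        warnings.warn("chi-squared test with expected cell count < 5")
    return {"table": table, "proportions": props, "chi2": float(chi2),
            "p_value": float(p), "dof": int(dof), "small_sample": small}


def expression_deciles(expression: pd.Series, n_bins: int = 10) -> pd.Series:
    """Equal-sample-size expression bins (decile labels 1..n_bins)."""
    return pd.qcut(expression.rank(method="first"), n_bins,
                   labels=range(1, n_bins + 1))


def density_by_expression(ies_counts: pd.Series, gene_lengths_kb: pd.Series,
                          expression: pd.Series, n_bins: int = 10
                          ) -> pd.DataFrame:
    """IES density (per kb) within expression bins of equal gene count."""
    deciles = expression_deciles(expression, n_bins)
    frame = pd.DataFrame({"decile": deciles, "n_ies": ies_counts,
                          "kb": gene_lengths_kb})
    grouped = frame.groupby("decile", observed=True).agg(
        n_ies=("n_ies", "sum"), kb=("kb", "sum"), n_genes=("n_ies", "size"))
    grouped["density_per_kb"] = grouped.n_ies / grouped.kb
    return grouped.reset_index()


def density_report(catalog_frame: pd.DataFrame, depth: np.ndarray,
                   min_depth: float = 15.0) -> dict:
    """IES density in MAC-destined sequence with sufficient MIC depth.

    ``depth`` is the per-base MIC read depth on the MAC assembly (all
    scaffolds concatenated is fine: only the qualifying length matters);
    IESs at positions below ``min_depth`` are excluded along with the
    region.
    """
    depth = np.asarray(depth, dtype=float)
    qualifying_bp = int((depth >= min_depth).sum())
    if qualifying_bp == 0:
        return {"density_per_kb": np.nan, "qualifying_kb": 0.0, "n_ies": 0}
    pos = catalog_frame["mac_position"].to_numpy()
    in_range = (pos >= 0) & (pos < len(depth))
    retained = int((depth[pos[in_range]] >= min_depth).sum())
    return {"density_per_kb": retained / (qualifying_bp / 1000.0),
            "qualifying_kb": qualifying_bp / 1000.0, "n_ies": retained}
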