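"""Disease-medication overlap of microbiota association sets.

For every disease x medication pair the module reports (i) the Phi
correlation of the two status vectors on pairwise-complete samples with
an FDR-adjusted p-value, and (ii) the Jaccard index between the two
phenotypes' sets of nominally associated microbiota traits.  A pair is
flagged eligible for overlap interpretation only when the Phi correlation
is FDR-significant and both phenotypes carry at least ``min_assoc``
(default 10) nominal associations -- small sets make the Jaccard index
unstable.
"""

from __future__ import annotations

import warnings

import pandas as pd

from microscan.phenotypes import phi_coefficient
from microscan.scan import benjamini_hochberg

__all__ = ["association_set", "jaccard_index", "build_overlap_table"]


def association_set(results: pd.DataFrame, phenotype: str, alpha: float = 0.05) -> set[str]:
    """Traits nominally associated (p < alpha, converged fit) with a phenotype."""
    if phenotype not in set(results["phenotype"]):
        raise KeyError(f"phenotype {phenotype!r} not present in results")
    sub = results[
        (results["phenotype"] == phenotype)
        & (results["status"] == "ok")
        & (results["p"] < alpha)
    ]
    return set(sub["trait"])


def jaccard_index(a: set, b: set) -> float:
    """|A n B| / |A u B|; defined as 0 when both sets are empty."""
    union = a | b
    if not union:
        warnings.warn("Jaccard of two empty sets defined as 0")
        return 0.0
    return len(a & b) / len(union)


def build_overlap_table(
    disease_results: pd.DataFrame,
    medication_results: pd.DataFrame,
    disease_table: pd.DataFrame,
    medication_table: pd.DataFrame,
    alpha: float = 0.05,
    fdr_alpha: float = 0.05,
    min_assoc: int = 10,
) -> pd.DataFrame:
    """Score all disease x medication pairs: Phi (with FDR) and Jaccard.

    ``disease_results``/``medication_results`` are association-scan frames
    for one scan variant on a shared trait set; the status tables supply
    the Phi correlations.  Output is sorted by Phi descending; pairs with
    undefined Phi (constant vectors) keep NaN entries and are ineligible.
    """
    shared = disease_table.index.intersection(medication_table.index)
    if len(shared) == 0:
        raise ValueError("disease and medication tables share no samples")
    diseases = [d for d in disease_table.columns if d in set(disease_results["phenotype"])]
    medications = [m for m in medication_table.columns if m in set(medication_results["phenotype"])]
    if not diseases or not medications:
        raise ValueError("no phenotypes shared between status tables and scan results")

    disease_sets = {d: association_set(disease_results, d, alpha) for d in diseases}
    medication_sets = {m: association_set(medication_results, m, alpha) for m in medications}

    rows = []
    for d in diseases:
        x = disease_table.loc[shared, d]
        for m in medications:
            y = medication_table.loc[shared, m]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                phi, p, n = phi_coefficient(x, y)
            sa, sb = disease_sets[d], medication_sets[m]
            rows.append(
                {
                    "disease": d,
                    "medication": m,
                    "phi": phi,
                    "phi_p": p,
                    "n_overlap_samples": n,
                    "n_assoc_disease": len(sa),
                    "n_assoc_medication": len(sb),
                    "jaccard": jaccard_index(sa, sb) if (sa or sb) else 0.0,
                }
            )
    table = pd.DataFrame(rows)
    defined = table["phi_p"].notna()
    table["phi_q"] = float("nan")
    if defined.any():
        table.loc[defined, "phi_q"] = benjamini_hochberg(table.loc[defined, "phi_p"].to_numpy())
    table["eligible"] = (
        (table["phi_q"] < fdr_alpha)
        & (table["n_assoc_disease"] >= min_assoc)
        & (table["n_assoc_medication"] >= min_assoc)
    ).fillna(False)
    return table.sort_values("phi", ascending=False, ignore_index=True)
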