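"""Assembly of the initial microbiota trait matrix.

Starting material is a sample x taxon count table with taxonomic lineages
(the output of an upstream OTU/ASV pipeline), optional precomputed alpha
diversity columns, and one or more beta-diversity distance matrices.  The
module collapses counts to class/family (or genus) level keeping only taxa
with complete assignment at that level, converts to log relative
abundances with a pseudocount, computes Shannon diversity and observed
richness, extracts principal-coordinate axes from each distance matrix,
and concatenates everything into a single samples x traits matrix with
per-trait kind metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

RANKS = ["kingdom", "phylum", "class", "order", "family", "genus"]

__all__ = [
    "RANKS",
    "TaxonCountTable",
    "parse_lineages",
    "collapse_to_level",
    "log_relative_abundance",
    "shannon_index",
    "richness",
    "alpha_diversity_table",
    "pcoa_axes",
    "assemble_initial_traits",
]


@dataclass
class TaxonCountTable:
    """Sample x taxon counts plus a taxa x rank lineage table.

    Lineage entries are plain rank names; an empty string marks an
    unassigned rank.
    """

    counts: pd.DataFrame
    lineage: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if not self.counts.columns.equals(self.lineage.index):
            if set(self.counts.columns) != set(self.lineage.index):
                raise ValueError("lineage index must match count-table taxa")
            self.lineage = self.lineage.loc[self.counts.columns]
        missing = [r for r in RANKS if r not in self.lineage.columns]
        if missing:
            raise ValueError(f"lineage table lacks ranks: {missing}")

    @property
    def depth(self) -> pd.Series:
        return self.counts.sum(axis=1)


def parse_lineages(lineages: pd.Series) -> pd.DataFrame:
    """Parse semicolon-delimited lineage strings (``k__Bacteria;p__...``).

    Greengenes-style single-letter prefixes are stripped; absent or empty
    fields become empty strings.
    """
    rows = []
    for taxon, s in lineages.items():
        fields = [f.strip() for f in str(s).split(";")]
        row = {}
        for rank, field in zip(RANKS, fields + [""] * (len(RANKS) - len(fields))):
            if len(field) >= 3 and field[1:3] == "__":
                field = field[3:]
            row[rank] = field.strip()
        rows.append(pd.Series(row, name=taxon))
    df = pd.DataFrame(rows, columns=RANKS).fillna("")
    df.index.name = "taxon"
    return df


def collapse_to_level(table: TaxonCountTable, level: str) -> TaxonCountTable:
    """Sum counts over taxa sharing the lineage prefix through ``level``.

    Taxa lacking a complete assignment through that level are excluded, so
    collapsed per-sample totals can fall below the original read depth.
    """
    if level not in {"class", "family", "genus"}:
        raise ValueError(f"unsupported collapse level: {level!r}")
    upto = RANKS[: RANKS.index(level) + 1]
    lineage = table.lineage
    complete = (lineage[upto] != "").all(axis=1)
    kept = lineage.loc[complete]
    keys = kept[upto].apply(lambda row: ";".join(row), axis=1)

    groups: dict[str, list[str]] = {}
    for taxon, key in keys.items():
        groups.setdefault(key, []).append(taxon)

    # short name = terminal rank, falling back to the full path on collision
    short = {key: key.rsplit(";", 1)[-1] for key in groups}
    seen: dict[str, list[str]] = {}
    for key, name in short.items():
        seen.setdefault(name, []).append(key)
    names = {key: (name if len(seen[name]) == 1 else key)
             for key, name in short.items()}

    ordered = sorted(groups)
    counts = pd.DataFrame(
        {names[key]: table.counts[groups[key]].sum(axis=1) for key in ordered},
        index=table.counts.index,
    )
    lin_rows = []
    for key in ordered:
        parts = key.split(";")
        row = {rank: parts[i] if i < len(parts) else "" for i, rank in enumerate(RANKS)}
        lin_rows.append(pd.Series(row, name=names[key]))
    new_lineage = pd.DataFrame(lin_rows, columns=RANKS)
    new_lineage.index.name = "taxon"
    return TaxonCountTable(counts=counts, lineage=new_lineage)


def log_relative_abundance(
    table: TaxonCountTable | pd.DataFrame, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Natural-log relative abundances with a per-count pseudocount.

    ``log((count + pc) / (depth + pc * n_taxa))`` -- the adjusted relative
    abundances still sum to 1 within each sample.
    """
    counts = table.counts if isinstance(table, TaxonCountTable) else table
    values = counts.to_numpy(dtype=float)
    depth = values.sum(axis=1)
    zero = depth <= 0
    if zero.any():
        bad = list(counts.index[zero])
        raise ValueError(f"zero-depth samples: {bad}")
    k = values.shape[1]
    rel = (values + pseudocount) / (depth + pseudocount * k)[:, None]
    return pd.DataFrame(np.log(rel), index=counts.index, columns=counts.columns)


def shannon_index(counts, base: float = 2.0) -> float:
    """Shannon diversity of one count vector (bits by default)."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    total = c.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero vector")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum() / np.log(base))


def richness(counts) -> int:
    """Number of taxa observed (count > 0)."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    return int((c > 0).sum())


def alpha_diversity_table(table: TaxonCountTable, base: float = 2.0) -> pd.DataFrame:
    """Per-sample Shannon index and observed richness."""
    rows = {
        s: (shannon_index(row, base=base), richness(row))
        for s, row in table.counts.iterrows()
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["shannon", "richness"])
    df = df.astype({"richness": float})
    df.index.name = "sample_id"
    return df


def pcoa_axes(distances: pd.DataFrame, k: int, prefix: str = "PCo") -> pd.DataFrame:
    """Top-``k`` classical-scaling (PCoA) axes of a distance matrix.

    Axes are ordered by descending eigenvalue; axes with non-positive
    eigenvalues (possible for non-Euclidean distances, where they are
    dropped with a warning from the eigendecomposition backend) are
    returned as zero columns when fewer than ``k`` positive axes exist.
    Eigenvalues are stored in ``result.attrs['eigenvalues']``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = distances.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.abs(np.diag(values)).max() > 1e-8:
        raise ValueError("distance matrix must have a zero diagonal")
    ids = [str(i) for i in distances.index]
    if not values.any():
        coords = np.zeros((len(ids), k))
        eigvals = np.zeros(k)
    else:
        res = _skbio_pcoa(DistanceMatrix(values, ids=ids), method="eigh")
        eig = res.eigvals.to_numpy()
        pos = eig > 1e-12 * max(eig.max(), 1.0)
        axes = res.samples.to_numpy()[:, pos]
        eigs = eig[pos]
        coords = np.zeros((len(ids), k))
        eigvals = np.zeros(k)
        take = min(k, axes.shape[1])
        coords[:, :take] = axes[:, :take]
        eigvals[:take] = eigs[:take]
    out = pd.DataFrame(
        coords, index=distances.index, columns=[f"{prefix}{i + 1}" for i in range(k)]
    )
    out.attrs["eigenvalues"] = eigvals
    return out


def assemble_initial_traits(
    counts: TaxonCountTable | None = None,
    alpha: pd.DataFrame | None = None,
    distance_matrices: dict[str, pd.DataFrame] | None = None,
    n_axes: int = 6,
    pseudocount: float = 0.5,
    levels: tuple[str, ...] = ("class", "family"),
) -> pd.DataFrame:
    """Concatenate taxon, alpha and ordination traits into one matrix.

    Trait names are namespaced by kind (``class:``, ``family:``,
    ``alpha:``, ``beta:``); per-trait kinds are stored in
    ``result.attrs['trait_metadata']``.
    """
    pieces: list[pd.DataFrame] = []
    kinds: dict[str, str] = {}
    index = None

    def add(df: pd.DataFrame, kind: str) -> None:
        nonlocal index
        if index is None:
            index = df.index
        elif not df.index.equals(index):
            if set(df.index) != set(index):
                raise ValueError(f"sample index mismatch for {kind} traits")
            df = df.loc[index]
        for c in df.columns:
            if c in kinds:
                raise ValueError(f"duplicate trait name: {c}")
            kinds[c] = kind
        pieces.append(df)

    if counts is not None:
        for level in levels:
            collapsed = collapse_to_level(counts, level)
            logged = log_relative_abundance(collapsed, pseudocount=pseudocount)
            logged.columns = [f"{level}:{c}" for c in logged.columns]
            add(logged, f"taxon_{level}")
    if alpha is not None:
        if alpha.shape[1] < 3:
            warnings.warn(
                f"only {alpha.shape[1]} alpha-diversity columns supplied (3 expected)"
            )
        named = alpha.copy()
        named.columns = [f"alpha:{c}" for c in named.columns]
        add(named, "alpha")
    for name, dm in (distance_matrices or {}).items():
        axes = pcoa_axes(dm, n_axes, prefix=f"beta:{name}_PCo")
        add(axes, "beta_axis")
    if not pieces:
        raise ValueError("no trait sources supplied")
    traits = pd.concat(pieces, axis=1)
    traits.index.name = "sample_id"
    traits.attrs["trait_metadata"] = pd.DataFrame(
        {"trait": list(kinds), "kind": list(kinds.values())}
    ).set_index("trait")
    return traits
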