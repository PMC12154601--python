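"""Elution-matrix assembly: PSM aggregation to orthogroups, abundance
filtering, species-level concatenation, and TSV round-trip.

The unit of evidence is the peptide-spectral match (PSM).  A PSM is counted
for an orthogroup only when every protein it matches belongs to that single
orthogroup; spectra whose matched proteins span two or more orthogroups are
discarded outright, which avoids double-counting shared peptides across
close paralogs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, ParseError, UnmappedProteinError

__all__ = [
    "OrthogroupMap",
    "PsmRecord",
    "ElutionMatrix",
    "aggregate_psms",
    "filter_min_abundance",
    "concatenate_by_species",
    "read_elution_tsv",
    "write_elution_tsv",
    "read_orthogroup_map",
]


@dataclass(frozen=True)
class OrthogroupMap:
    """Many-to-one protein -> orthogroup assignment with species labels."""

    protein_to_og: dict[str, str]
    protein_species: dict[str, str]

    def orthogroups(self, proteins) -> set[str]:
        missing = {p for p in proteins if p not in self.protein_to_og}
        if missing:
            raise UnmappedProteinError(missing)
        return {self.protein_to_og[p] for p in proteins}


@dataclass(frozen=True)
class PsmRecord:
    """One spectrum assignment: fraction index plus the matched protein set."""

    experiment_id: str
    fraction: int
    proteins: frozenset[str]
    count: int = 1

    def __post_init__(self):
        if not self.proteins:
            raise ParameterError("PSM record with empty protein set")
        if self.fraction < 0:
            raise ParameterError(f"negative fraction index {self.fraction}")


@dataclass
class ElutionMatrix:
    """Orthogroup x fraction count matrix for one experiment (or one
    species-level concatenation of experiments)."""

    experiment_id: str
    data: pd.DataFrame  # index: orthogroup IDs; columns: fraction labels

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate row IDs: {dups}")
        if (self.data.to_numpy() < 0).any():
            raise ParameterError("negative counts in elution matrix")

    @property
    def orthogroups(self) -> pd.Index:
        return self.data.index

    @property
    def n_fractions(self) -> int:
        return self.data.shape[1]

    def row_totals(self) -> pd.Series:
        return self.data.sum(axis=1)


def aggregate_psms(
    records: list[PsmRecord],
    og_map: OrthogroupMap,
    experiment_id: str,
    n_fractions: int | None = None,
) -> ElutionMatrix:
    """Sum uniquely-attributable PSMs into an orthogroup x fraction matrix.

    A record whose matched proteins all map to one orthogroup contributes
    its count to that orthogroup's cell; a record spanning >= 2 orthogroups
    contributes nothing.  Unmapped proteins raise, listing the offenders.
    """
    missing = {
        p for r in records for p in r.proteins if p not in og_map.protein_to_og
    }
    if missing:
        raise UnmappedProteinError(missing)

    if n_fractions is None:
        n_fractions = max((r.fraction for r in records), default=-1) + 1
    counts: dict[str, np.ndarray] = {}
    for r in records:
        if r.fraction >= n_fractions:
            raise ParameterError(
                f"fraction {r.fraction} outside experiment bounds (<{n_fractions})"
            )
        ogs = {og_map.protein_to_og[p] for p in r.proteins}
        if len(ogs) != 1:
            continue  # ambiguous across orthogroups: discard
        og = next(iter(ogs))
        row = counts.setdefault(og, np.zeros(n_fractions, dtype=np.int64))
        row[r.fraction] += r.count

    data = pd.DataFrame.from_dict(counts, orient="index", dtype=np.int64)
    if data.empty:
        data = pd.DataFrame(
            np.zeros((0, n_fractions), dtype=np.int64),
            columns=range(n_fractions),
        )
    data = data.sort_index()
    data.columns = [f"frac{i}" for i in range(n_fractions)]
    return ElutionMatrix(experiment_id, data)


def filter_min_abundance(
    matrices: list[ElutionMatrix], min_total_psms: float = 60
) -> tuple[set[str], list[ElutionMatrix]]:
    """Keep orthogroups whose PSM total over ALL supplied matrices reaches
    ``min_total_psms`` (inclusive); drop the others from every matrix.

    Returns the retained orthogroup set and the filtered matrices.
    """
    if not matrices:
        raise ParameterError("filter_min_abundance requires >= 1 matrix")
    totals: dict[str, float] = {}
    for m in matrices:
        for og, t in m.row_totals().items():
            totals[og] = totals.get(og, 0) + float(t)
    retained = {og for og, t in totals.items() if t >= min_total_psms}
    filtered = [
        ElutionMatrix(m.experiment_id, m.data.loc[m.data.index.isin(retained)])
        for m in matrices
    ]
    return retained, filtered


def concatenate_by_species(
    matrices_by_species: dict[str, list[ElutionMatrix]],
) -> dict[str, ElutionMatrix]:
    """Concatenate each species' experiments column-wise into one matrix.

    Rows are the union of orthogroups; an orthogroup absent from one
    experiment gets zeros in that experiment's columns.  Column labels are
    prefixed with the experiment ID to stay unique.
    """
    out: dict[str, ElutionMatrix] = {}
    for species, mats in matrices_by_species.items():
        if not mats:
            raise ParameterError(f"species {species!r} has no matrices")
        ids = [m.experiment_id for m in mats]
        if len(set(ids)) != len(ids):
            raise ParameterError(
                f"duplicate experiment IDs within species {species!r}: {ids}"
            )
        blocks = []
        for m in mats:
            blk = m.data.copy()
            blk.columns = [f"{m.experiment_id}__{c}" for c in blk.columns]
            blocks.append(blk)
        cat = pd.concat(blocks, axis=1).fillna(0)
        cat = cat.astype(np.int64 if all(
            np.issubdtype(b.dtypes.iloc[0], np.integer) for b in blocks if b.shape[1]
        ) else float).sort_index()
        out[species] = ElutionMatrix(f"{species}_concat", cat)
    return out


def write_elution_tsv(matrix: ElutionMatrix, path: str | Path) -> None:
    """Wide TSV: first column ``orthogroup``, one column per fraction."""
    df = matrix.data.copy()
    df.index.name = "orthogroup"
    df.to_csv(path, sep="\t")


def read_elution_tsv(
    path: str | Path,
    experiment_id: str | None = None,
    sep: str = "\t",
    strict_int: bool = True,
) -> ElutionMatrix:
    """Parse a wide elution TSV with validation.

    Raises :class:`ParseError` with a line number for ragged rows,
    duplicate row IDs or non-numeric cells.  With ``strict_int`` off,
    float-valued cells (expectation-mode simulations) are accepted.
    """
    path = Path(path)
    rows: list[tuple[str, list[float]]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
        if len(header) < 2:
            raise ParseError(f"{path.name}:1: expected ID column plus fractions")
        ncol = len(header) - 1
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split(sep)
            if len(cells) != ncol + 1:
                raise ParseError(
                    f"{path.name}:{lineno}: ragged row ({len(cells)} fields, "
                    f"expected {ncol + 1})"
                )
            og = cells[0]
            if og in seen:
                raise ParseError(f"{path.name}:{lineno}: duplicate row ID {og!r}")
            seen.add(og)
            try:
                vals = [float(c) for c in cells[1:]]
            except ValueError as exc:
                raise ParseError(f"{path.name}:{lineno}: non-numeric cell: {exc}")
            if strict_int and any(v != int(v) for v in vals):
                raise ParseError(
                    f"{path.name}:{lineno}: non-integer count with strict_int on"
                )
            rows.append((og, vals))
    data = pd.DataFrame(
        [v for _, v in rows],
        index=[og for og, _ in rows],
        columns=header[1:],
        dtype=np.int64 if strict_int else float,
    )
    return ElutionMatrix(experiment_id or path.stem, data)


def read_orthogroup_map(path: str | Path) -> OrthogroupMap:
    """3-column TSV: protein, orthogroup, species."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["protein", "orthogroup", "species"], dtype=str)
    if df["protein"].duplicated().any():
        dups = df.loc[df["protein"].duplicated(), "protein"].tolist()
        raise ParseError(f"protein mapped more than once: {dups[:5]}")
    return OrthogroupMap(
        dict(zip(df["protein"], df["orthogroup"])),
        dict(zip(df["protein"], df["species"])),
    )
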