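"""Core data structures for case-parent triads with parental phenotypes.

Genotypes are counts (0/1/2) of the designated variant allele.  A *triad*
is an affected child plus both biological parents; ascertainment is always
"child affected", so the child's disease indicator is implicit.  Parental
disease status is recorded for the mother (``D_M``) and, in two-sex
designs, for the father (``D_F``).

The genotype cell space is the set of Mendelian-consistent ordered
``(M, F, C)`` combinations — exactly 15 of them — cross-classified by the
parental phenotype strata.  Cells are stored in a fixed lexicographic
order ``(mating_type, M, F, C, D_M[, D_F])`` so parameter vectors and
count arrays are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

GENOTYPES = (0, 1, 2)

#: Unordered parental genotype pairs, in canonical order.  ``mating_type``
#: returns 1-based indices into this tuple.
MATING_PAIRS = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))


def mendelian_transmission_prob(m: int, f: int, c: int) -> float:
    """Probability that parents with ``m`` and ``f`` copies of the variant
    allele produce a child carrying ``c`` copies, under Mendelian
    transmission at an autosomal biallelic locus.
    """
    for g, name in ((m, "m"), (f, "f"), (c, "c")):
        if g not in GENOTYPES:
            raise ValueError(f"genotype {name}={g!r} not in 0/1/2")
    # a parent with g copies transmits the variant with probability g/2
    pm, pf = m / 2.0, f / 2.0
    probs = {
        0: (1 - pm) * (1 - pf),
        1: pm * (1 - pf) + (1 - pm) * pf,
        2: pm * pf,
    }
    return probs[c]


def mating_type(m: int, f: int) -> int:
    """1-based index (1..6) of the unordered parental genotype pair."""
    if m not in GENOTYPES or f not in GENOTYPES:
        raise ValueError(f"genotypes ({m!r}, {f!r}) not in 0/1/2")
    return MATING_PAIRS.index((min(m, f), max(m, f))) + 1


def _genotype_cells() -> list[tuple[int, int, int, int]]:
    cells = []
    for m in GENOTYPES:
        for f in GENOTYPES:
            for c in GENOTYPES:
                if mendelian_transmission_prob(m, f, c) > 0:
                    cells.append((mating_type(m, f), m, f, c))
    cells.sort()
    return cells


#: The 15 Mendelian-consistent (mating_type, M, F, C) combinations,
#: sorted lexicographically.  All count arrays index this list.
GENO_CELLS: tuple[tuple[int, int, int, int], ...] = tuple(_genotype_cells())
N_GENO_CELLS = len(GENO_CELLS)  # 15

# Convenience arrays for vectorised likelihood code.
CELL_MT = np.array([g[0] - 1 for g in GENO_CELLS])       # 0-based mating type
CELL_M = np.array([g[1] for g in GENO_CELLS])
CELL_F = np.array([g[2] for g in GENO_CELLS])
CELL_C = np.array([g[3] for g in GENO_CELLS])
#: ln(2) offset on the (M=1, F=1, C=1) cell: two heterozygous parents have
#: two equally likely ways to produce a heterozygous child.
CELL_LOGW = np.where((CELL_M == 1) & (CELL_F == 1) & (CELL_C == 1), np.log(2.0), 0.0)
CELL_MEND = np.array(
    [mendelian_transmission_prob(m, f, c) for (_, m, f, c) in GENO_CELLS]
)
_CELL_INDEX = {g[1:]: i for i, g in enumerate(GENO_CELLS)}


def genotype_cell_index(m: int, f: int, c: int) -> int:
    """Position of ordered ``(m, f, c)`` in :data:`GENO_CELLS`."""
    try:
        return _CELL_INDEX[(m, f, c)]
    except KeyError:
        raise ValueError(f"(M={m}, F={f}, C={c}) is not Mendelian-consistent")


@dataclass(frozen=True)
class TriadCell:
    """One cell of the (genotype x parental-phenotype) table."""

    M: int
    F: int
    C: int
    D_M: int
    D_F: Optional[int] = None

    @property
    def mating_type(self) -> int:
        return mating_type(self.M, self.F)


def enumerate_cells(design: str = "one_sex") -> list[TriadCell]:
    """All cells of the triad table, in canonical order.

    ``one_sex`` designs stratify by the mother's phenotype only (30 cells);
    ``two_sex`` designs add the father's phenotype (60 cells).
    """
    if design not in ("one_sex", "two_sex"):
        raise ValueError(f"unknown design {design!r}")
    cells = []
    for (_, m, f, c) in GENO_CELLS:
        for d_m in (0, 1):
            if design == "one_sex":
                cells.append(TriadCell(m, f, c, d_m))
            else:
                for d_f in (0, 1):
                    cells.append(TriadCell(m, f, c, d_m, d_f))
    return cells


@dataclass
class TriadRecord:
    """One family: child genotype, parental genotypes and phenotypes.

    ``M``/``F`` may be ``None`` (missing); the child genotype ``C`` is
    required.  ``D_F`` is ``None`` for one-sex designs.
    """

    family_id: str
    M: Optional[int]
    F: Optional[int]
    C: int
    D_M: int
    D_F: Optional[int] = None

    def __post_init__(self):
        if self.C not in GENOTYPES:
            raise ValueError(f"family {self.family_id}: child genotype {self.C!r}")
        for g, name in ((self.M, "M"), (self.F, "F")):
            if g is not None and g not in GENOTYPES:
                raise ValueError(f"family {self.family_id}: {name}={g!r}")
        for d, name in ((self.D_M, "D_M"), (self.D_F, "D_F")):
            if d is not None and d not in (0, 1):
                raise ValueError(f"family {self.family_id}: {name}={d!r}")

    @property
    def complete(self) -> bool:
        return self.M is not None and self.F is not None

    def is_consistent(self) -> bool:
        """Mendelian consistency of the observed genotypes."""
        if not self.complete:
            ms = GENOTYPES if self.M is None else (self.M,)
            fs = GENOTYPES if self.F is None else (self.F,)
            return any(
                mendelian_transmission_prob(m, f, self.C) > 0
                for m in ms
                for f in fs
            )
        return mendelian_transmission_prob(self.M, self.F, self.C) > 0


class CellCountTable:
    """Nonnegative (possibly fractional) counts over the triad cell space.

    Counts are held as an array of shape ``(15, 2)`` for one-sex designs
    (genotype cell x D_M) or ``(15, 2, 2)`` for two-sex designs
    (genotype cell x D_M x D_F).  Fractional counts arise as expected
    counts under a scenario and as E-step completions.
    """

    def __init__(self, counts: np.ndarray, design: str = "one_sex"):
        counts = np.asarray(counts, dtype=float)
        expected = (N_GENO_CELLS, 2) if design == "one_sex" else (N_GENO_CELLS, 2, 2)
        if design not in ("one_sex", "two_sex"):
            raise ValueError(f"unknown design {design!r}")
        if counts.shape != expected:
            raise ValueError(f"counts shape {counts.shape}, expected {expected}")
        if np.any(counts < -1e-12):
            raise ValueError("negative cell count")
        self.counts = np.clip(counts, 0.0, None)
        self.design = design

    @classmethod
    def zeros(cls, design: str = "one_sex") -> "CellCountTable":
        shape = (N_GENO_CELLS, 2) if design == "one_sex" else (N_GENO_CELLS, 2, 2)
        return cls(np.zeros(shape), design)

    @classmethod
    def from_records(
        cls, records: Iterable[TriadRecord], design: Optional[str] = None
    ) -> "CellCountTable":
        return tabulate(records, design=design)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def genotype_margin(self) -> np.ndarray:
        """Counts per genotype cell, summed over phenotype strata (length 15)."""
        axes = tuple(range(1, self.counts.ndim))
        return self.counts.sum(axis=axes)

    def mother_strata(self) -> np.ndarray:
        """(15, 2) counts by mother's phenotype (two-sex tables collapse D_F)."""
        if self.design == "one_sex":
            return self.counts
        return self.counts.sum(axis=2)

    def father_strata(self) -> np.ndarray:
        """(15, 2) counts by father's phenotype (two-sex only)."""
        if self.design == "one_sex":
            raise ValueError("one-sex table has no father phenotype stratum")
        return self.counts.sum(axis=1)

    def get(self, m: int, f: int, c: int, d_m: int, d_f: Optional[int] = None) -> float:
        i = genotype_cell_index(m, f, c)
        if self.design == "one_sex":
            return float(self.counts[i, d_m])
        return float(self.counts[i, d_m, 0 if d_f is None else d_f])

    def add(self, m, f, c, d_m, d_f=None, weight: float = 1.0) -> None:
        i = genotype_cell_index(m, f, c)
        if self.design == "one_sex":
            self.counts[i, d_m] += weight
        else:
            self.counts[i, d_m, d_f] += weight

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, (mt, m, f, c) in enumerate(GENO_CELLS):
            if self.design == "one_sex":
                for d_m in (0, 1):
                    rows.append((mt, m, f, c, d_m, self.counts[i, d_m]))
            else:
                for d_m in (0, 1):
                    for d_f in (0, 1):
                        rows.append((mt, m, f, c, d_m, d_f, self.counts[i, d_m, d_f]))
        cols = ["mating_type", "M", "F", "C", "D_M"]
        if self.design == "two_sex":
            cols.append("D_F")
        return pd.DataFrame(rows, columns=cols + ["count"])

    def __repr__(self) -> str:
        return (
            f"<CellCountTable design={self.design} total={self.total:.6g} "
            f"cells={self.counts.size}>"
        )


def tabulate(
    records: Iterable[TriadRecord], design: Optional[str] = None
) -> CellCountTable:
    """Cross-tabulate complete triad records into a :class:`CellCountTable`.

    Raises if any record has a missing parental genotype (those belong on
    the EM path) or is Mendelian-inconsistent.
    """
    records = list(records)
    if design is None:
        design = (
            "two_sex"
            if records and all(r.D_F is not None for r in records)
            else "one_sex"
        )
    table = CellCountTable.zeros(design)
    for rec in records:
        if not rec.complete:
            raise ValueError(
                f"family {rec.family_id} has a missing parental genotype; "
                "use the EM-capable joint model for incomplete data"
            )
        if not rec.is_consistent():
            raise ValueError(
                f"family {rec.family_id}: genotypes (M={rec.M}, F={rec.F}, "
                f"C={rec.C}) are Mendelian-inconsistent"
            )
        d_f = rec.D_F if design == "two_sex" else None
        if design == "two_sex" and d_f is None:
            raise ValueError(f"family {rec.family_id}: D_F required for two-sex table")
        table.add(rec.M, rec.F, rec.C, rec.D_M, d_f)
    return table


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_MISSING_TSV = {"NA", "-1", ""}


def read_triads(path, format: str = "tsv", snp: Optional[str] = None,
                variant_allele: Optional[str] = None) -> list[TriadRecord]:
    """Read triad records from a TSV table or a PED-like pedigree file.

    TSV columns: ``family_id  M  F  C  D_M  [D_F]`` with a header line;
    missing genotypes coded ``NA`` or ``-1``.  The PED dialect has one
    line per individual (FID IID PAT MAT SEX PHENO A1 A2); triads are
    reconstructed from the PAT/MAT pointers, ``0 0`` allele pairs are
    missing, and genotypes count copies of ``variant_allele`` (default:
    the minor allele in the file).
    """
    if format == "tsv":
        return _read_tsv(path)
    if format == "ped":
        return _read_ped(path, snp=snp, variant_allele=variant_allele)
    raise ValueError(f"unknown format {format!r}")


def _parse_geno(tok: str) -> Optional[int]:
    tok = tok.strip()
    if tok in _MISSING_TSV:
        return None
    return int(tok)


def _read_tsv(path) -> list[TriadRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        required = ["family_id", "M", "F", "C", "D_M"]
        if header[: len(required)] != required:
            raise ValueError(f"{path}: expected header starting {required}, got {header}")
        has_df = len(header) > 5 and header[5] == "D_F"
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            toks = line.split("\t")
            if len(toks) < 5:
                raise ValueError(f"{path}:{lineno}: expected >=5 fields, got {len(toks)}")
            try:
                c = _parse_geno(toks[3])
                if c is None:
                    warnings.warn(
                        f"{path}:{lineno}: family {toks[0]} has a missing child "
                        "genotype; record excluded"
                    )
                    continue
                rec = TriadRecord(
                    family_id=toks[0],
                    M=_parse_geno(toks[1]),
                    F=_parse_geno(toks[2]),
                    C=c,
                    D_M=int(toks[4]),
                    D_F=int(toks[5]) if has_df and toks[5].strip() not in _MISSING_TSV else None,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            records.append(rec)
    return records


def write_triads(records: Sequence[TriadRecord], path) -> None:
    """Write records as the TSV dialect read back by :func:`read_triads`."""
    has_df = any(r.D_F is not None for r in records)
    cols = ["family_id", "M", "F", "C", "D_M"] + (["D_F"] if has_df else [])
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            row = [
                r.family_id,
                "NA" if r.M is None else str(r.M),
                "NA" if r.F is None else str(r.F),
                str(r.C),
                str(r.D_M),
            ]
            if has_df:
                row.append("NA" if r.D_F is None else str(r.D_F))
            fh.write("\t".join(row) + "\n")


def _read_ped(path, snp: Optional[str] = None,
              variant_allele: Optional[str] = None) -> list[TriadRecord]:
    """PED-like pedigree reader (single SNP, or column pair chosen by 0-based
    ``snp`` index for multi-SNP files)."""
    individuals: dict[tuple[str, str], dict] = {}
    col = 0 if snp is None else int(snp)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks:
                continue
            if len(toks) < 8 + 2 * col:
                raise ValueError(f"{path}:{lineno}: expected >= {8 + 2 * col} fields")
            fid, iid, pat, mat, _sex, pheno = toks[:6]
            a1, a2 = toks[6 + 2 * col], toks[7 + 2 * col]
            individuals[(fid, iid)] = {
                "pat": pat, "mat": mat, "pheno": pheno, "alleles": (a1, a2),
                "line": lineno,
            }
    # choose variant allele: explicit, else minor allele over typed individuals
    allele_counts: dict[str, int] = {}
    for info in individuals.values():
        for a in info["alleles"]:
            if a != "0":
                allele_counts[a] = allele_counts.get(a, 0) + 1
    if not allele_counts:
        return []
    if len(allele_counts) > 2:
        raise ValueError(f"{path}: more than two alleles at the analyzed SNP")
    if variant_allele is None:
        variant_allele = min(allele_counts, key=lambda a: (allele_counts[a], a))

    def geno(info) -> Optional[int]:
        a1, a2 = info["alleles"]
        if a1 == "0" or a2 == "0":
            return None
        return int(a1 == variant_allele) + int(a2 == variant_allele)

    def affected(info) -> Optional[int]:
        # PLINK convention: 2 affected, 1 unaffected, 0/-9 missing
        p = info["pheno"]
        if p in ("0", "-9"):
            return None
        return 1 if p == "2" else 0

    records = []
    for (fid, iid), info in individuals.items():
        if info["pat"] == "0" or info["mat"] == "0":
            continue  # a founder, not a case child
        father = individuals.get((fid, info["pat"]))
        mother = individuals.get((fid, info["mat"]))
        if father is None or mother is None:
            warnings.warn(f"{path}: family {fid} child {iid}: parents not found; skipped")
            continue
        c = geno(info)
        if c is None:
            warnings.warn(
                f"{path}: family {fid} child {iid} has a missing genotype; excluded"
            )
            continue
        d_m = affected(mother)
        records.append(
            TriadRecord(
                family_id=fid,
                M=geno(mother),
                F=geno(father),
                C=c,
                D_M=0 if d_m is None else d_m,
                D_F=affected(father),
            )
        )
    records.sort(key=lambda r: r.family_id)
    return records
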