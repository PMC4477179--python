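"""Scenario generator: expected triad-cell frequencies and study simulation.

A scenario specifies one or more Hardy-Weinberg subpopulations (allele
frequency, maternal baseline risk, optional father baseline risk, and a
relative child baseline risk used when subpopulations differ), genetic
relative risks, a study size and parental-genotype missingness rates.
The generative story, per subpopulation:

1. parents drawn independently under HWE, the child by Mendelian
   transmission;
2. the child is ascertained as affected, which weights each triad cell by
   the child's baseline risk times the offspring relative risk ``R_C``
   and the maternally-mediated relative risk ``S_M``;
3. the mother of an affected child is herself affected with probability
   ``MBR * Rm_M`` (maternal baseline risk times the mother's own
   genotype relative risk); in two-sex designs the father is affected
   independently with probability ``FBR * Rf_F``.

Admixture mixes subpopulations in proportion to their population weight
times their probability of producing an affected child, then the table is
scaled to the study size ``n``.  Studies are simulated as a single
multinomial draw over the cells; missingness masks each parent's genotype
independently at the given rate, leaving phenotypes intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .data import (
    CELL_C,
    CELL_F,
    CELL_M,
    CELL_MEND,
    CellCountTable,
    GENO_CELLS,
    N_GENO_CELLS,
    TriadRecord,
)


def _hwe(p: float) -> np.ndarray:
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])


def grandmaternal_factor(p: float, s: np.ndarray) -> np.ndarray:
    """Apparent risk multiplier on a parent's own phenotype induced by a
    maternally-mediated effect acting through the *grand*mother.

    A maternally-mediated relative risk ``S`` operates on every child via
    its mother's genotype — including on the study parents themselves, via
    the grandmothers.  A parent's genotype ``G`` is correlated with the
    grandmaternal genotype, so ``S`` confounds the parent's own
    genotype-phenotype relationship even when the variant has no inherited
    effect.  The factor returned is ``E[S^Ggm | G=g] / E[S^Ggm | G=0]``
    for g = 0, 1, 2, under HWE at allele frequency ``p`` (for S1 = 1.4 and
    p = 0.3 this gives the apparent risks 1 : 1.2 : 1.4).
    """
    hw = _hwe(p)
    f = np.empty(3)
    for g in range(3):
        post = np.empty(3)
        for j in range(3):
            a = j / 2.0
            trans = [(1 - a) * (1 - p), (1 - a) * p + a * (1 - p), a * p][g]
            post[j] = trans * hw[j]
        post /= post.sum()
        f[g] = post @ s
    return f / f[0]


def _rr_vector(r1: float, r2: Optional[float]) -> np.ndarray:
    """(1, R1, R2); R2 defaults to R1^2 (log-additive)."""
    if r2 is None:
        r2 = r1 * r1
    return np.array([1.0, r1, r2])


@dataclass
class Subpopulation:
    """One homogeneous HWE stratum of the source population."""

    weight: float = 1.0
    allele_freq: float = 0.3
    mbr: float = 0.2            # disease risk in non-carrier mothers of cases
    fbr: Optional[float] = None  # same for fathers (two-sex designs)
    child_risk: float = 1.0     # baseline child risk, relative across subpops


@dataclass
class ScenarioSpec:
    """Full generative specification of a simulated triad study."""

    subpops: Sequence[Subpopulation] = field(
        default_factory=lambda: [Subpopulation()]
    )
    r1: float = 1.0             # offspring relative risks (child's genotype)
    r2: Optional[float] = None
    s1: float = 1.0             # maternally-mediated relative risks
    s2: Optional[float] = None
    rm1: float = 1.0            # mother's genotype on her own phenotype
    rm2: Optional[float] = None
    rf1: float = 1.0            # father's genotype on his phenotype (two-sex)
    rf2: Optional[float] = None
    n: int = 300
    missing_father_rate: float = 0.0
    missing_mother_rate: float = 0.0

    @property
    def design(self) -> str:
        return "two_sex" if any(s.fbr is not None for s in self.subpops) else "one_sex"

    def validate(self) -> None:
        w = sum(s.weight for s in self.subpops)
        if not np.isclose(w, 1.0):
            raise ValueError(f"subpopulation weights sum to {w}, not 1")
        for name, v in (("r1", self.r1), ("s1", self.s1), ("rm1", self.rm1),
                        ("rf1", self.rf1)):
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        rm = _rr_vector(self.rm1, self.rm2)
        rf = _rr_vector(self.rf1, self.rf2)
        s = _rr_vector(self.s1, self.s2)
        for sp in self.subpops:
            if not 0 < sp.allele_freq < 1:
                raise ValueError(f"allele frequency {sp.allele_freq} outside (0,1)")
            conf = grandmaternal_factor(sp.allele_freq, s).max()
            if sp.mbr * rm.max() * conf > 1 + 1e-12:
                raise ValueError(
                    f"MBR {sp.mbr} x max maternal risk factor "
                    f"{rm.max() * conf:g} exceeds 1"
                )
            if sp.fbr is not None and sp.fbr * rf.max() * conf > 1 + 1e-12:
                raise ValueError(
                    f"FBR {sp.fbr} x max paternal risk factor "
                    f"{rf.max() * conf:g} exceeds 1"
                )
        for rate in (self.missing_father_rate, self.missing_mother_rate):
            if not 0 <= rate <= 1:
                raise ValueError(f"missingness rate {rate} outside [0,1]")

    @classmethod
    def homogeneous(cls, allele_freq: float = 0.3, mbr: float = 0.2,
                    fbr: Optional[float] = None, **kw) -> "ScenarioSpec":
        return cls(subpops=[Subpopulation(1.0, allele_freq, mbr, fbr)], **kw)

    @classmethod
    def from_toml(cls, path) -> "ScenarioSpec":
        """Load a scenario from a flat TOML file with ``[[subpops]]`` tables."""
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        subpops = [Subpopulation(**sp) for sp in raw.pop("subpops", [{}])]
        spec = cls(subpops=subpops, **raw)
        spec.validate()
        return spec


def expected_cell_frequencies(spec: ScenarioSpec) -> CellCountTable:
    """Expected counts over the triad cell space, scaled to total ``spec.n``."""
    spec.validate()
    design = spec.design
    r = _rr_vector(spec.r1, spec.r2)
    s = _rr_vector(spec.s1, spec.s2)
    rm = _rr_vector(spec.rm1, spec.rm2)
    rf = _rr_vector(spec.rf1, spec.rf2)

    shape = (N_GENO_CELLS, 2) if design == "one_sex" else (N_GENO_CELLS, 2, 2)
    acc = np.zeros(shape)
    for sp in spec.subpops:
        hw = _hwe(sp.allele_freq)
        # unnormalized affected-child triad frequencies in this subpopulation
        t = (
            hw[CELL_M] * hw[CELL_F] * CELL_MEND
            * sp.child_risk * r[CELL_C] * s[CELL_M]
        )
        # maternally-mediated effects also act on the parents themselves,
        # through the grandmothers; conditional on the parent's genotype
        # this shows up as an apparent risk factor on the parent phenotype
        conf = grandmaternal_factor(sp.allele_freq, s)
        p_dm = np.clip(sp.mbr * rm[CELL_M] * conf[CELL_M], 0.0, 1.0)
        if design == "one_sex":
            contrib = np.stack([t * (1 - p_dm), t * p_dm], axis=1)
        else:
            p_df = np.clip(sp.fbr * rf[CELL_F] * conf[CELL_F], 0.0, 1.0)
            contrib = np.einsum(
                "i,ij,ik->ijk",
                t,
                np.stack([1 - p_dm, p_dm], axis=1),
                np.stack([1 - p_df, p_df], axis=1),
            )
        acc += sp.weight * contrib
    acc *= spec.n / acc.sum()
    return CellCountTable(acc, design)


def simulate_counts(
    spec: ScenarioSpec, rng: Union[int, np.random.Generator]
) -> CellCountTable:
    """One simulated study as a multinomial draw over the cell table."""
    rng = np.random.default_rng(rng)
    expected = expected_cell_frequencies(spec)
    probs = expected.counts.ravel() / expected.total
    draw = rng.multinomial(spec.n, probs).reshape(expected.counts.shape)
    return CellCountTable(draw.astype(float), expected.design)


def _records_from_counts(table: CellCountTable) -> list[TriadRecord]:
    records = []
    fid = 0
    it = np.ndindex(table.counts.shape)
    for idx in it:
        count = int(round(table.counts[idx]))
        _, m, f, c = GENO_CELLS[idx[0]]
        d_m = idx[1]
        d_f = idx[2] if table.design == "two_sex" else None
        for _ in range(count):
            fid += 1
            records.append(TriadRecord(f"fam{fid:05d}", m, f, c, d_m, d_f))
    return records


def simulate_study(
    spec: ScenarioSpec, rng: Union[int, np.random.Generator]
) -> list[TriadRecord]:
    """Simulate ``spec.n`` triad records (including missingness, if any)."""
    rng = np.random.default_rng(rng)
    records = _records_from_counts(simulate_counts(spec, rng))
    if spec.missing_father_rate > 0 or spec.missing_mother_rate > 0:
        records = apply_missingness(records, spec, rng)
    return records


def apply_missingness(
    records: Sequence[TriadRecord],
    spec: ScenarioSpec,
    rng: Union[int, np.random.Generator],
) -> list[TriadRecord]:
    """Mask parental genotypes independently at the scenario's rates.

    Masking is independent of the genotype values (noninformative
    missingness); phenotypes are never masked.
    """
    rng = np.random.default_rng(rng)
    out = []
    mask_f = rng.random(len(records)) < spec.missing_father_rate
    mask_m = rng.random(len(records)) < spec.missing_mother_rate
    for rec, mf, mm in zip(records, mask_f, mask_m):
        out.append(
            TriadRecord(
                rec.family_id,
                None if mm else rec.M,
                None if mf else rec.F,
                rec.C,
                rec.D_M,
                rec.D_F,
            )
        )
    return out
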