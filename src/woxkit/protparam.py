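"""Protein physicochemical profiles: MW, theoretical pI, instability index,
aliphatic index and GRAVY.

The default constant tables are the canonical ones of the ExPASy lineage:
average residue masses, the Guruprasad dipeptide instability weights (DIWV)
and Kyte–Doolittle hydropathy values, taken from biopython's data modules.
The pI is the bisection root of the Henderson–Hasselbalch net charge with a
Bjellqvist-style pKa set; alternative pKa sets can be supplied, since
published ExPASy values depend on the exact table version.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Data.IUPACData import protein_weights as _AA_WEIGHTS
from Bio.SeqUtils.ProtParamData import DIWV as _DIWV
from Bio.SeqUtils.ProtParamData import kd as _KD

__all__ = [
    "PKaSet",
    "PhysChemProfile",
    "WATER_MASS",
    "molecular_weight",
    "net_charge",
    "isoelectric_point",
    "instability_index",
    "aliphatic_index",
    "gravy",
    "profile",
    "profile_batch",
]

WATER_MASS = 18.01524  # Da, released per peptide bond

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

# Average residue masses = free amino-acid mass − water.
RESIDUE_MASSES = {aa: _AA_WEIGHTS[aa] - WATER_MASS for aa in STANDARD_AA}


@dataclass(frozen=True)
class PKaSet:
    """Ionizable-group pKa values used by the net-charge model.

    Defaults follow the Bjellqvist-style values of the ExPASy lineage;
    cysteine is treated as ionizable (reduced form).
    """

    name: str = "bjellqvist"
    n_terminus: float = 7.5
    c_terminus: float = 3.55
    side_chains: dict[str, float] = field(
        default_factory=lambda: {
            "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
            "H": 5.98, "K": 10.0, "R": 12.0,
        }
    )

    def __post_init__(self) -> None:
        for v in (self.n_terminus, self.c_terminus, *self.side_chains.values()):
            if not 0 < v < 14:
                raise ValueError("pKa values must lie in (0, 14)")


@dataclass
class PhysChemProfile:
    id: str
    length: int
    mw: float
    pi: float
    instability: float
    stability_class: str
    aliphatic: float
    gravy: float


def _check(seq: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError("empty protein sequence")
    bad = set(seq) - STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residue(s): {sorted(bad)}")
    return seq


def molecular_weight(seq: str) -> float:
    """Average molecular mass in Da: sum of residue masses plus one water."""
    seq = _check(seq)
    return sum(RESIDUE_MASSES[a] for a in seq) + WATER_MASS


def net_charge(seq: str, ph: float, pka: PKaSet | None = None) -> float:
    """Signed Henderson–Hasselbalch net charge at a given pH.

    Positive groups (N-terminus, H, K, R) contribute 1/(1+10^(pH−pKa));
    negative groups (C-terminus, D, E, C, Y) contribute −1/(1+10^(pKa−pH)).
    Strictly decreasing in pH.
    """
    if not 0 <= ph <= 14:
        raise ValueError("pH must lie in [0, 14]")
    seq = _check(seq)
    pka = pka or PKaSet()
    pos = [pka.n_terminus] + [pka.side_chains[a] for a in seq if a in "HKR"]
    neg = [pka.c_terminus] + [pka.side_chains[a] for a in seq if a in "DECY"]
    charge = sum(1.0 / (1.0 + 10.0 ** (ph - p)) for p in pos)
    charge -= sum(1.0 / (1.0 + 10.0 ** (p - ph)) for p in neg)
    return charge


def isoelectric_point(seq: str, pka: PKaSet | None = None, tol: float = 1e-3) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    The charge is strictly decreasing, positive at pH 0 and negative at
    pH 14, so the root exists and is unique; bisection runs to ``tol``.
    """
    pka = pka or PKaSet()
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def instability_index(seq: str, diwv: dict[str, dict[str, float]] | None = None) -> float:
    """Guruprasad instability index: (10/L) * sum of dipeptide weights over
    consecutive residue pairs.  II >= 40 classifies the protein unstable."""
    seq = _check(seq)
    if len(seq) < 2:
        raise ValueError("instability index needs at least 2 residues")
    diwv = diwv if diwv is not None else _DIWV
    total = sum(diwv[a][b] for a, b in zip(seq, seq[1:]))
    return 10.0 / len(seq) * total


def stability_class(ii: float) -> str:
    return "stable" if ii < 40.0 else "unstable"


def aliphatic_index(seq: str) -> float:
    """Ikai aliphatic index from mole percentages of A, V, I and L:
    AI = X_Ala + 2.9*X_Val + 3.9*(X_Ile + X_Leu)."""
    seq = _check(seq)
    n = len(seq)
    x = {a: 100.0 * seq.count(a) / n for a in "AVIL"}
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


def gravy(seq: str, kd: dict[str, float] | None = None) -> float:
    """Grand average of hydropathy (Kyte–Doolittle); negative = hydrophilic."""
    seq = _check(seq)
    kd = kd if kd is not None else _KD
    return sum(kd[a] for a in seq) / len(seq)


def profile(seq: str, rec_id: str = "", pka: PKaSet | None = None) -> PhysChemProfile:
    """Full physicochemical profile of one protein sequence."""
    seq = _check(seq)
    ii = instability_index(seq) if len(seq) >= 2 else float("nan")
    return PhysChemProfile(
        id=rec_id,
        length=len(seq),
        mw=molecular_weight(seq),
        pi=isoelectric_point(seq, pka),
        instability=ii,
        stability_class=stability_class(ii),
        aliphatic=aliphatic_index(seq),
        gravy=gravy(seq),
    )


def profile_batch(records, pka: PKaSet | None = None) -> pd.DataFrame:
    """Profiles for a family of SequenceRecords as a DataFrame
    (id, length, MW_Da, pI, instability, class, aliphatic, GRAVY)."""
    rows = []
    for rec in records:
        p = profile(rec.residues.rstrip("*"), rec.id, pka)
        rows.append(
            {
                "id": p.id, "length": p.length, "MW_Da": p.mw, "pI": p.pi,
                "instability": p.instability, "class": p.stability_class,
                "aliphatic": p.aliphatic, "GRAVY": p.gravy,
            }
        )
    return pd.DataFrame(rows)
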