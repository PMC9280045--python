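"""Codon-usage bias statistics for gene sets.

For a synonymous family of size k with per-codon counts X_i:

    RSCU_i = X_i * k / sum(X)          (1 = no bias, >1 positive, <1 negative)
    RFSC_i = 100 * X_i / sum(X)        (percent of the family's usage)

A codon is *high-frequency* when its RFSC exceeds 60% or is at least 1.5x the
family's average frequency 100/k; single-codon families (Met, Trp) are never
classified.  Two gene sets' usage is compared per codon as the ratio of their
per-mille frequencies: ratios <= 0.50 or >= 2.00 (inclusive) mark divergent
usage, anything strictly inside the band is similar — the basis for choosing
a heterologous expression host.

Codons are represented as RNA triplets (AUG, GCA, ...); DNA input is
converted on counting.  Stop codons form a family of their own (TER, k=3)
and take part in every per-codon statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .io_formats import CodonTable, SequenceRecord, standard_codon_table

__all__ = [
    "SynonymousFamily",
    "CodonCounts",
    "CodonUsageTable",
    "RatioTable",
    "synonymous_families",
    "count_codons",
    "compute_usage",
    "usage_from_printed",
    "bias_partition",
    "consensus_high_frequency",
    "codon_frequency",
    "ratio_compare",
    "ratio_from_printed",
    "rank_hosts",
    "load_fixture_usage_tables",
    "load_fixture_ratio_tables",
]

_EPS = 1e-9
_BASE_ORDER = {b: i for i, b in enumerate("UCAG")}


def _rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


def _codon_key(codon: str):
    return tuple(_BASE_ORDER[b] for b in codon)


@dataclass(frozen=True)
class SynonymousFamily:
    """All codons encoding one amino acid (or the stop family 'TER')."""

    amino_acid: str
    codons: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.codons)


def synonymous_families(table: CodonTable | None = None) -> list[SynonymousFamily]:
    """Partition the 64 RNA codons into synonymous families.

    Families are ordered by amino-acid letter (TER last); codons within a
    family follow the U<C<A<G base order of codon-usage tables.
    """
    table = table or standard_codon_table()
    groups: dict[str, list[str]] = {}
    for codon, aa in table.forward.items():
        groups.setdefault(aa, []).append(_rna(codon))
    fams = [
        SynonymousFamily(aa, tuple(sorted(codons, key=_codon_key)))
        for aa, codons in groups.items()
    ]
    fams.sort(key=lambda f: ("\x7f" if f.amino_acid == "TER" else f.amino_acid))
    assert sum(f.k for f in fams) == 64
    return fams


def _codon_universe(families: list[SynonymousFamily]) -> list[str]:
    return [c for f in families for c in f.codons]


@dataclass
class CodonCounts:
    """Frame-0 codon occurrence counts over a set of CDS records."""

    label: str
    counts: dict[str, int]
    n_skipped: int = 0

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())


def count_codons(
    cds_set: list[SequenceRecord], label: str = "cds_set"
) -> CodonCounts:
    """Count frame-0 triplets over all records; triplets containing non-ACGT
    characters are skipped and tallied in ``n_skipped``."""
    families = synonymous_families()
    counts = {c: 0 for c in _codon_universe(families)}
    skipped = 0
    for rec in cds_set:
        seq = rec.residues
        if len(seq) % 3 != 0:
            raise ValueError(
                f"record {rec.id!r}: length {len(seq)} not divisible by 3"
            )
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if set(codon) - set("ACGT"):
                skipped += 1
            else:
                counts[_rna(codon)] += 1
    return CodonCounts(label, counts, skipped)


@dataclass
class CodonUsageTable:
    """Per-codon usage statistics for one gene set.

    ``df`` is indexed by RNA codon with columns amino_acid, k, count, rscu,
    rfsc, bias, high_frequency.  ``bias`` is positive/negative/none, or
    undefined for families never observed; ``high_frequency`` is boolean,
    pd.NA for single-codon families and unobserved families.
    """

    label: str
    df: pd.DataFrame

    def high_frequency_set(self) -> set[str]:
        return set(self.df.index[self.df["high_frequency"] == True])  # noqa: E712

    def bias_of(self, codon: str) -> str:
        return self.df.loc[_rna(codon), "bias"]

    def to_tsv(self, target) -> None:
        out = self.df.reset_index().rename(columns={"index": "codon"})
        out.to_csv(target, sep="\t", index=False, float_format="%.2f")


def _classify_bias(rscu: float) -> str:
    if math.isnan(rscu):
        return "undefined"
    if rscu > 1.0 + _EPS:
        return "positive"
    if rscu < 1.0 - _EPS:
        return "negative"
    return "none"


def _classify_hf(rfsc: float, k: int) -> object:
    if math.isnan(rfsc) or k < 2:
        return pd.NA
    return bool(rfsc > 60.0 or rfsc >= 1.5 * (100.0 / k) - _EPS)


def compute_usage(
    counts: CodonCounts, families: list[SynonymousFamily] | None = None
) -> CodonUsageTable:
    """RSCU/RFSC, bias class and high-frequency flag from raw codon counts."""
    families = families or synonymous_families()
    rows = []
    for fam in families:
        total = sum(counts.counts[c] for c in fam.codons)
        for codon in fam.codons:
            x = counts.counts[codon]
            if total > 0:
                rscu = x * fam.k / total
                rfsc = 100.0 * x / total
            else:
                rscu = rfsc = float("nan")
            rows.append(
                {
                    "codon": codon,
                    "amino_acid": fam.amino_acid,
                    "k": fam.k,
                    "count": x,
                    "rscu": rscu,
                    "rfsc": rfsc,
                    "bias": _classify_bias(rscu),
                    "high_frequency": _classify_hf(rfsc, fam.k),
                }
            )
    df = pd.DataFrame(rows).set_index("codon")
    return CodonUsageTable(counts.label, df)


def usage_from_printed(
    label: str,
    rscu: dict[str, float],
    rfsc: dict[str, float],
    families: list[SynonymousFamily] | None = None,
) -> CodonUsageTable:
    """Build a usage table from already-rounded published RSCU/RFSC columns.

    Classification uses the printed 2-decimal values verbatim (a printed
    RSCU of exactly 1.00 is 'none'); counts are unavailable and set to -1.
    """
    families = families or synonymous_families()
    rows = []
    for fam in families:
        for codon in fam.codons:
            r, f = rscu[codon], rfsc[codon]
            rows.append(
                {
                    "codon": codon,
                    "amino_acid": fam.amino_acid,
                    "k": fam.k,
                    "count": -1,
                    "rscu": r,
                    "rfsc": f,
                    "bias": _classify_bias(r),
                    "high_frequency": _classify_hf(f, fam.k),
                }
            )
    df = pd.DataFrame(rows).set_index("codon")
    return CodonUsageTable(label, df)


def bias_partition(
    tables: list[CodonUsageTable],
) -> tuple[int, int, int, int]:
    """Across gene sets, count codons with identical positive / negative /
    no bias, and codons whose bias class differs between sets.

    The four counts sum to 64.  A codon uniformly 'undefined' (family never
    observed in any set) is counted with the no-bias class.
    """
    if not tables:
        raise ValueError("bias_partition requires at least one table")
    universe = list(tables[0].df.index)
    for t in tables[1:]:
        if list(t.df.index) != universe:
            raise ValueError("tables cover different codon sets")
    n_pos = n_neg = n_none = n_diff = 0
    for codon in universe:
        classes = {t.df.loc[codon, "bias"] for t in tables}
        if len(classes) > 1:
            n_diff += 1
        elif classes == {"positive"}:
            n_pos += 1
        elif classes == {"negative"}:
            n_neg += 1
        else:
            n_none += 1
    return n_pos, n_neg, n_none, n_diff


def consensus_high_frequency(tables: list[CodonUsageTable]) -> set[str]:
    """Codons classified high-frequency in every gene set."""
    if not tables:
        raise ValueError("consensus requires at least one table")
    result = tables[0].high_frequency_set()
    for t in tables[1:]:
        result &= t.high_frequency_set()
    return result


def codon_frequency(counts: CodonCounts) -> dict[str, float]:
    """Per-codon usage in occurrences per 1,000 codons."""
    n = counts.n_total
    if n == 0:
        raise ValueError("cannot compute frequencies of an empty codon set")
    return {c: 1000.0 * x / n for c, x in counts.counts.items()}


@dataclass
class RatioTable:
    """Per-codon frequency ratio of a gene set vs a reference genome.

    ``df`` indexed by codon with columns freq_set,
    freq_ref, ratio, class (similar / divergent / undefined)."""

    pair_label: str
    df: pd.DataFrame

    def divergent_set(self) -> set[str]:
        return set(self.df.index[self.df["class"] == "divergent"])

    @property
    def n_divergent(self) -> int:
        return int((self.df["class"] == "divergent").sum())

    def to_tsv(self, target) -> None:
        out = self.df.reset_index().rename(columns={"index": "codon"})
        out.to_csv(target, sep="\t", index=False, float_format="%.2f")


def _ratio_class(ratio: float, lo: float, hi: float) -> str:
    if math.isnan(ratio):
        return "undefined"
    return "divergent" if (ratio <= lo + _EPS or ratio >= hi - _EPS) else "similar"


def ratio_compare(
    freq_set: dict[str, float],
    freq_ref: dict[str, float],
    pair_label: str = "set_vs_ref",
    lo: float = 0.5,
    hi: float = 2.0,
) -> RatioTable:
    """Classify each codon's frequency ratio against the similarity band.

    The band is inclusive at both ends: r <= ``lo`` or r >= ``hi`` is
    divergent.  A codon used by the set but absent from the reference is
    divergent with an undefined ratio; a codon absent from both is undefined.
    """
    families = synonymous_families()
    rows = []
    for codon in _codon_universe(families):
        fs = freq_set[_rna(codon)] if _rna(codon) in freq_set else freq_set[codon]
        fr = freq_ref[_rna(codon)] if _rna(codon) in freq_ref else freq_ref[codon]
        if fr > 0:
            ratio = fs / fr
            cls = _ratio_class(ratio, lo, hi)
        elif fs > 0:
            ratio = float("nan")
            cls = "divergent"
        else:
            ratio = float("nan")
            cls = "undefined"
        rows.append(
            {"codon": _rna(codon), "freq_set": fs, "freq_ref": fr,
             "ratio": ratio, "class": cls}
        )
    return RatioTable(pair_label, pd.DataFrame(rows).set_index("codon"))


def ratio_from_printed(
    pair_label: str, ratios: dict[str, float], lo: float = 0.5, hi: float = 2.0
) -> RatioTable:
    """Ratio table from already-rounded published ratio columns (frequencies
    unavailable, set to NaN); classification uses the printed values."""
    rows = [
        {"codon": _rna(c), "freq_set": float("nan"), "freq_ref": float("nan"),
         "ratio": r, "class": _ratio_class(r, lo, hi)}
        for c, r in ratios.items()
    ]
    return RatioTable(pair_label, pd.DataFrame(rows).set_index("codon"))


def rank_hosts(
    freq_set: dict[str, float],
    candidate_refs: dict[str, dict[str, float]],
    lo: float = 0.5,
    hi: float = 2.0,
) -> list[tuple[str, int, float]]:
    """Rank candidate expression hosts by codon-usage compatibility.

    Hosts are sorted by ascending number of divergent codons; ties are broken
    by the mean |log2 ratio| over non-stop codons with a defined ratio, then
    by label, so the ranking is deterministic.
    """
    if not candidate_refs:
        raise ValueError("rank_hosts requires at least one candidate")
    stops = {c for f in synonymous_families() for c in f.codons if f.amino_acid == "TER"}
    results = []
    for label, freq_ref in candidate_refs.items():
        table = ratio_compare(freq_set, freq_ref, pair_label=label, lo=lo, hi=hi)
        ratios = table.df.loc[~table.df.index.isin(stops), "ratio"]
        defined = ratios[(ratios > 0) & np.isfinite(ratios)]
        mean_log = float(np.abs(np.log2(defined)).mean()) if len(defined) else float("inf")
        results.append((label, table.n_divergent, mean_log))
    results.sort(key=lambda t: (t[1], t[2], t[0]))
    return results


# ------------------------------------------------------------------ worked-example data

_SPECIES = ("HbWOX", "JcWOX", "MeWOX", "RcWOX")
_HOSTS = ("At", "Nt", "Pt", "Os")


def _fixture_path(name: str):
    return resources.files("woxkit").joinpath("data", "fixtures", name)


def load_fixture_usage_tables() -> dict[str, CodonUsageTable]:
    """The published per-species RSCU/RFSC columns as usage tables.

    Values are the printed 2-decimal numbers; three stop-codon cells of the
    JcWOX column are internally inconsistent in print and carry anomaly=1 in
    the fixture file.
    """
    with _fixture_path("table1_rscu_rfsc.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    tables = {}
    for label, prefix in zip(_SPECIES, ("hb", "jc", "me", "rc")):
        rscu = dict(zip(df["codon"], df[f"{prefix}_rscu"]))
        rfsc = dict(zip(df["codon"], df[f"{prefix}_rfsc"]))
        tables[label] = usage_from_printed(label, rscu, rfsc)
    return tables


def load_fixture_ratio_tables() -> dict[str, RatioTable]:
    """The published codon-frequency-ratio columns (gene set vs host genome),
    keyed 'JcWOX/At'-style."""
    with _fixture_path("table2_ratios.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    tables = {}
    for label, sp in zip(_SPECIES, ("hb", "jc", "me", "rc")):
        for host in _HOSTS:
            key = f"{label}/{host}"
            col = f"{sp}_{host.lower()}"
            tables[key] = ratio_from_printed(key, dict(zip(df["codon"], df[col])))
    return tables


def load_fixture_table1() -> pd.DataFrame:
    """Raw transcription of the published RSCU/RFSC table, anomaly flags included."""
    with _fixture_path("table1_rscu_rfsc.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
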