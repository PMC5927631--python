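"""Per-cell per-year rate of driver mutations in a coding sequence.

The genome-wide substitution rate (mutations per year per cell) is split
across the 96 strand-collapsed (trinucleotide context x alternate base)
classes in proportion to an observed mutation spectrum, then divided by the
number of genomic sites carrying each context to give a per-site per-year
rate for every class.  Enumerating all ``3L`` single-base substitutions of a
coding sequence, annotating their protein consequence, and summing the class
rates over the substitutions that qualify as drivers yields the driver
substitution rate.  Driver indel rates come from the cohort-level linear
relation between indel and substitution counts, treating all indels inside
the CDS as drivers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

BASES = ("A", "C", "G", "T")
PYRIMIDINES = ("C", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = set(_CODON_TABLE.stop_codons)
START_CODON = "ATG"


def _translate_codon(codon: str) -> str:
    if codon in STOP_CODONS:
        return "*"
    return _CODON_TABLE.forward_table[codon]


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def pyrimidine_class(context: str, alt: str) -> tuple[str, str]:
    """Collapse a (trinucleotide, alternate base) pair to the pyrimidine strand."""
    if context[1] in PYRIMIDINES:
        return context, alt
    return reverse_complement(context), _COMPLEMENT[alt]


def all_classes() -> list[str]:
    """The 96 strand-collapsed substitution classes, as ``"ACA>T"`` strings."""
    classes = []
    for mid in PYRIMIDINES:
        for five, three in product(BASES, BASES):
            ctx = five + mid + three
            for alt in BASES:
                if alt != mid:
                    classes.append(f"{ctx}>{alt}")
    return classes


def all_contexts() -> list[str]:
    """The 32 pyrimidine-centred trinucleotide contexts."""
    return sorted({c.split(">")[0] for c in all_classes()})


@dataclass(frozen=True)
class MutationSpectrum:
    """Counts per 96-class plus the genome-wide substitution rate per year."""

    counts: dict  # class string -> count
    total_rate: float  # substitutions / cell / year, genome-wide

    def __post_init__(self):
        known = set(all_classes())
        unknown = set(self.counts) - known
        if unknown:
            raise ValueError(f"unknown spectrum classes: {sorted(unknown)[:5]}")
        vals = np.array(list(self.counts.values()), dtype=float)
        if np.any(vals < 0):
            raise ValueError("spectrum counts must be >= 0")
        if vals.sum() == 0:
            raise ValueError("spectrum must have at least one non-zero class")

    def fractions(self) -> dict:
        total = sum(self.counts.values())
        return {cls: cnt / total for cls, cnt in self.counts.items() if cnt > 0}


def spectrum_context_rates(
    spectrum: MutationSpectrum,
    genome_context_counts: dict,
    total_rate: float | None = None,
) -> dict:
    """Per-site per-year rate for each of the 96 substitution classes.

    ``rate(class) = total_rate * fraction(class) / sites(context(class))``.
    Contexts absent from ``genome_context_counts`` but observed in the
    spectrum are an error.  The conservation identity
    ``sum_class rate * sites = total_rate`` holds by construction.
    """
    if total_rate is None:
        total_rate = spectrum.total_rate
    rates = {}
    for cls, frac in spectrum.fractions().items():
        ctx = cls.split(">")[0]
        sites = genome_context_counts.get(ctx)
        if sites is None or sites <= 0:
            raise ValueError(f"context {ctx} observed in spectrum but missing from genome counts")
        rates[cls] = total_rate * frac / sites
    return rates


def uniform_context_counts(sites_per_context: float = 1.0) -> dict:
    """A flat genome context table, for fully synthetic tests."""
    return {ctx: sites_per_context for ctx in all_contexts()}


def enumerate_cds_substitutions(cds: str, flank5: str = "A", flank3: str = "A") -> pd.DataFrame:
    """All single-base substitutions of a CDS with protein consequences.

    The CDS must be a multiple of 3, start with ATG, end with a stop codon
    and contain no internal stops.  ``flank5``/``flank3`` supply the bases
    adjacent to the CDS so edge positions get a trinucleotide context.

    Returns a frame with one row per substitution (``3L`` rows): pos (0-based
    in the CDS), ref, alt, codon_index, ref_aa, alt_aa, consequence (one of
    synonymous / missense / start_lost / stop_lost / stop_gained), and the
    strand-collapsed class (context + alt on the pyrimidine strand).
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if set(cds) - set(BASES):
        raise ValueError("CDS contains non-ACGT characters")
    if cds[:3] != START_CODON:
        raise ValueError("CDS must start with ATG")
    if cds[-3:] not in STOP_CODONS:
        raise ValueError("CDS must end with a stop codon")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for idx, codon in enumerate(codons[:-1]):
        if idx > 0 and codon in STOP_CODONS:
            raise ValueError(f"internal stop codon at codon {idx}")

    padded = flank5[-1:] + cds + flank3[:1]
    n_codons = len(codons)
    records = []
    for pos, ref in enumerate(cds):
        codon_index = pos // 3
        codon_pos = pos % 3
        ref_codon = codons[codon_index]
        ref_aa = _translate_codon(ref_codon)
        context = padded[pos : pos + 3]
        for alt in BASES:
            if alt == ref:
                continue
            alt_codon = ref_codon[:codon_pos] + alt + ref_codon[codon_pos + 1 :]
            alt_aa = _translate_codon(alt_codon)
            if codon_index == 0:
                consequence = "start_lost" if alt_codon != START_CODON else "synonymous"
            elif ref_aa == "*":
                consequence = "synonymous" if alt_aa == "*" else "stop_lost"
            elif alt_aa == "*":
                consequence = "stop_gained"
            elif alt_aa == ref_aa:
                consequence = "synonymous"
            else:
                consequence = "missense"
            ctx_pyr, alt_pyr = pyrimidine_class(context, alt)
            records.append(
                {
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "codon_index": codon_index,
                    "ref_aa": ref_aa,
                    "alt_aa": alt_aa,
                    "consequence": consequence,
                    "mut_class": f"{ctx_pyr}>{alt_pyr}",
                }
            )
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class DriverConsequenceSet:
    """Which substitution consequences count as drivers.

    ``missense`` holds admissible (1-based protein position, alternate
    residue) pairs, e.g. previously observed hotspot substitutions.
    """

    start_lost: bool = True
    stop_lost: bool = True
    stop_gained: bool = True
    missense: frozenset = field(default_factory=frozenset)
    indels_in_cds: bool = True

    def matches(self, row) -> bool:
        if row.consequence == "start_lost":
            return self.start_lost
        if row.consequence == "stop_lost":
            return self.stop_lost
        if row.consequence == "stop_gained":
            return self.stop_gained
        if row.consequence == "missense":
            return (row.codon_index + 1, row.alt_aa) in self.missense
        return False


def driver_substitution_rate(annotated: pd.DataFrame, drivers: DriverConsequenceSet, class_rates) -> float:
    """Sum of per-site class rates over driver-qualifying substitutions.

    ``class_rates`` is either a dict mapping class -> per-site per-year rate
    or a scalar uniform rate.
    """
    total = 0.0
    for row in annotated.itertuples(index=False):
        if not drivers.matches(row):
            continue
        if np.isscalar(class_rates):
            total += float(class_rates)
        else:
            total += float(class_rates.get(row.mut_class, 0.0))
    return total


def indel_driver_rate(
    substitution_counts,
    indel_counts,
    substitution_rate: float,
    cds_length: int,
    genome_size: float,
) -> float:
    """Driver indel rate per cell per year from the cohort indel:substitution slope.

    A zero-intercept least-squares fit of per-patient indel counts on
    substitution counts gives slope ``s``; the indel rate per year is then
    ``s * substitution_rate`` and the CDS-restricted driver rate is that
    scaled by ``cds_length / genome_size`` (all indels inside the CDS count
    as drivers).
    """
    x = np.asarray(substitution_counts, dtype=float)
    y = np.asarray(indel_counts, dtype=float)
    if len(x) < 2:
        raise ValueError("need counts for >= 2 patients")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("counts must be >= 0")
    if np.all(x == 0):
        raise ValueError("all substitution counts are zero")
    slope = float(np.dot(x, y) / np.dot(x, x))
    return slope * substitution_rate * cds_length / genome_size


@dataclass(frozen=True)
class DriverRates:
    """Driver substitution, indel, and total rate, per cell per year."""

    substitution_rate: float
    indel_rate: float

    @property
    def total(self) -> float:
        return self.substitution_rate + self.indel_rate


def total_driver_rate(substitution_rate: float, indel_rate: float) -> DriverRates:
    """Combine component rates into the total per-cell per-year driver rate."""
    if substitution_rate < 0 or indel_rate < 0:
        raise ValueError("component rates must be >= 0")
    return DriverRates(substitution_rate=substitution_rate, indel_rate=indel_rate)


def round_sigfigs(x: float, sig: int = 2) -> float:
    """Round half away from zero to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    from decimal import Decimal, ROUND_HALF_UP

    d = Decimal(repr(x))
    exponent = d.adjusted()  # floor(log10(|x|))
    quantum = Decimal(1).scaleb(exponent - sig + 1)
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))
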