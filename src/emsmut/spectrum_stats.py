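"""Substitution spectra, mutation densities, zygosity and uniqueness.

The 12 raw substitution types collapse into 6 strand-symmetric classes
(a change and its reverse complement are one class): the two transitions
GC>AT and AT>GC, and the four transversions GC>TA, GC>CG, AT>CG, AT>TA.
EMS chemistry predicts dominance of GC>AT (O6-alkylguanine pairing with T).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .codon_model import is_transition
from .variant_io import Variant, VariantSet

log = logging.getLogger(__name__)

COLLAPSED_CLASSES = ("GC>AT", "AT>GC", "GC>TA", "GC>CG", "AT>CG", "AT>TA")

#: raw type -> collapsed class (strand pairing)
_COLLAPSE = {
    "C>T": "GC>AT", "G>A": "GC>AT",
    "A>G": "AT>GC", "T>C": "AT>GC",
    "C>A": "GC>TA", "G>T": "GC>TA",
    "C>G": "GC>CG", "G>C": "GC>CG",
    "A>C": "AT>CG", "T>G": "AT>CG",
    "A>T": "AT>TA", "T>A": "AT>TA",
}
RAW_TYPES = tuple(_COLLAPSE)


def classify_substitution(ref: str, alt: str) -> tuple[str, str, str]:
    """(raw type, collapsed class, 'transition'|'transversion') for a SNP."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT" or len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"invalid substitution alleles {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"ref equals alt ({ref})")
    raw = f"{ref}>{alt}"
    return raw, _COLLAPSE[raw], "transition" if is_transition(ref, alt) else "transversion"


@dataclass
class SpectrumTable:
    """Counts and percent frequencies over raw and collapsed classes."""

    raw_counts: dict[str, int]
    collapsed_counts: dict[str, int]
    n_total: int
    n_skipped_indels: int = 0

    @property
    def frequencies(self) -> dict[str, float] | None:
        """Percent per collapsed class; None for an empty table."""
        if self.n_total == 0:
            return None
        return {c: 100.0 * n / self.n_total for c, n in self.collapsed_counts.items()}

    @property
    def raw_frequencies(self) -> dict[str, float] | None:
        if self.n_total == 0:
            return None
        return {t: 100.0 * n / self.n_total for t, n in self.raw_counts.items()}


def spectrum_table(variants) -> SpectrumTable:
    """Tally the substitution spectrum of an iterable of variants.

    InDels are skipped (their count is recorded); an empty input yields a
    table with undefined (None) frequencies.
    """
    raw = {t: 0 for t in RAW_TYPES}
    collapsed = {c: 0 for c in COLLAPSED_CLASSES}
    skipped = 0
    total = 0
    for v in variants:
        if not v.is_snp:
            skipped += 1
            continue
        raw_t, coll, _ = classify_substitution(v.ref, v.alt)
        raw[raw_t] += 1
        collapsed[coll] += 1
        total += 1
    if skipped:
        log.info("spectrum: skipped %d InDels", skipped)
    return SpectrumTable(raw, collapsed, total, skipped)


@dataclass
class DensityStat:
    """Mutation density as kb per mutation over a stated denominator."""

    scope: str
    n_variants: int
    denominator_bp: int
    kb_per_mutation: float | None

    @property
    def defined(self) -> bool:
        return self.kb_per_mutation is not None


def mutation_density(n_variants: int, denominator_bp: int, scope: str = "whole_genome") -> DensityStat:
    """kb of sequence per mutation: denominator_bp / n / 1000.

    Zero variants yields an explicit undefined result rather than an
    arithmetic error. Class-restricted densities pass the restricted count
    with the same denominator; CDS densities pass total CDS bp.
    """
    if denominator_bp <= 0:
        raise ValueError("denominator_bp must be positive")
    if n_variants == 0:
        return DensityStat(scope, 0, denominator_bp, None)
    return DensityStat(scope, n_variants, denominator_bp, denominator_bp / n_variants / 1000.0)


def zygosity_fractions(variants) -> dict[str, float] | None:
    """Percent hom / het over variants of known zygosity; None if all unknown."""
    hom = het = 0
    for v in variants:
        if v.zygosity == "hom":
            hom += 1
        elif v.zygosity == "het":
            het += 1
    known = hom + het
    if known == 0:
        return None
    return {"hom": 100.0 * hom / known, "het": 100.0 * het / known}


def per_contig_counts(variants) -> dict[str, int]:
    """SNP+InDel counts per contig (a partition of the total)."""
    counts: dict[str, int] = {}
    for v in variants:
        counts[v.contig] = counts.get(v.contig, 0) + 1
    return counts


@dataclass
class UniqueStats:
    per_line_unique: dict[str, int]
    per_line_total: dict[str, int]
    per_line_percent: dict[str, float]
    population_unique_total: int


def unique_snps(population: list[VariantSet]) -> UniqueStats:
    """Per-line counts of variants present in exactly one line.

    A variant key carried by two or more lines is shared (not unique
    anywhere); the population unique total sums the per-line uniques.
    """
    if len(population) < 2:
        raise ValueError("unique_snps needs at least 2 lines")
    ids = [vs.line_id for vs in population]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate line_ids: {ids}")
    occurrence: dict[tuple, int] = {}
    for vs in population:
        for key in vs.keys:
            occurrence[key] = occurrence.get(key, 0) + 1
    per_unique, per_total, per_pct = {}, {}, {}
    for vs in population:
        uniq = sum(1 for key in vs.keys if occurrence[key] == 1)
        per_unique[vs.line_id] = uniq
        per_total[vs.line_id] = len(vs)
        per_pct[vs.line_id] = 100.0 * uniq / len(vs) if len(vs) else float("nan")
    return UniqueStats(
        per_line_unique=per_unique,
        per_line_total=per_total,
        per_line_percent=per_pct,
        population_unique_total=sum(per_unique.values()),
    )


def percent_unique_vs_panel(line: VariantSet, panel: list[VariantSet]) -> float | None:
    """Percent of a line's variants absent from every background panel set."""
    if len(line) == 0:
        return None
    panel_keys: set[tuple] = set()
    for vs in panel:
        panel_keys |= vs.keys
    novel = len(line.keys - panel_keys)
    return 100.0 * novel / len(line)
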