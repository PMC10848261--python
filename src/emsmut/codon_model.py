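"""Genetic-code neighborhood model of random mutagenesis.

Every sense codon has exactly nine single-nucleotide variants (three
positions x three alternative bases). Enumerating and labeling those
variants yields the theoretical amino-acid substitution matrix expected
when point mutations strike codons at random, the set of amino-acid change
types accessible by one substitution, and per-codon mutagenicity ratios
relative to codon usage. EMS strongly biases which of the nine neighbors
are realized (transitions over transversions), so the observed/theoretical
ratio separates mutational accessibility from mutagen chemistry.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from Bio.Data import CodonTable

log = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

_standard = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TO_AA[_stop] = "*"
SENSE_CODONS = frozenset(c for c, aa in CODON_TO_AA.items() if aa != "*")
STOP_CODONS = frozenset(_standard.stop_codons)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


def is_transition(ref: str, alt: str) -> bool:
    return (ref, alt) in TRANSITIONS


def translate_codon(codon: str) -> str:
    """Amino acid (one-letter) or '*' for a stop codon."""
    try:
        return CODON_TO_AA[codon.upper()]
    except KeyError:
        raise ValueError(f"invalid codon {codon!r}") from None


@dataclass(frozen=True)
class CodonVariant:
    """One single-nucleotide neighbor of a codon."""

    codon: str
    position: int  # 0-based within the codon
    ref_base: str
    alt_base: str
    variant_codon: str
    from_aa: str
    to_aa: str  # '*' for stop_gain targets
    kind: str  # synonymous | missense | stop_gain
    substitution: str  # transition | transversion


def codon_neighbors(codon: str) -> list[CodonVariant]:
    """The nine labeled single-nucleotide variants of a sense codon."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    from_aa = translate_codon(codon)
    out = []
    for pos in range(3):
        ref = codon[pos]
        for alt in BASES:
            if alt == ref:
                continue
            var = codon[:pos] + alt + codon[pos + 1 :]
            to_aa = translate_codon(var)
            if to_aa == "*":
                kind = "stop_gain"
            elif to_aa == from_aa:
                kind = "synonymous"
            else:
                kind = "missense"
            out.append(
                CodonVariant(
                    codon=codon,
                    position=pos,
                    ref_base=ref,
                    alt_base=alt,
                    variant_codon=var,
                    from_aa=from_aa,
                    to_aa=to_aa,
                    kind=kind,
                    substitution="transition" if is_transition(ref, alt) else "transversion",
                )
            )
    return out


def all_directed_changes() -> list[CodonVariant]:
    """All 549 single-nucleotide changes of the 61 sense codons."""
    out = []
    for codon in sorted(SENSE_CODONS):
        out.extend(codon_neighbors(codon))
    return out


@dataclass
class TheoreticalMatrix:
    """Expected percent of each amino-acid change under random mutation.

    ``expected[from_aa][to_aa]`` is the percentage of the included
    single-nucleotide changes from ``from_aa`` codons that land on
    ``to_aa``. With the default convention only missense (sense-to-sense,
    different amino acid) changes enter the denominator; rows then sum
    to 100 for every amino acid.
    """

    mode: str  # all | transition_only | transversion_only
    weighting: str  # uniform | usage
    include_stop_gain: bool
    include_synonymous: bool
    expected: dict[str, dict[str, float]] = field(default_factory=dict)

    def get(self, from_aa: str, to_aa: str) -> float:
        return self.expected.get(from_aa, {}).get(to_aa, 0.0)


def theoretical_aa_matrix(
    mode: str = "all",
    weighting: str = "uniform",
    usage=None,
    include_stop_gain_in_denominator: bool = False,
    include_synonymous_in_denominator: bool = False,
) -> TheoreticalMatrix:
    """Theoretical amino-acid change percentages under random mutation.

    For each source amino acid, pool the single-nucleotide changes of all
    its codons (each codon weighted uniformly, or by its within-group
    usage), restrict to the included change kinds, and report each
    target's share as a percent. ``mode`` restricts to transitions or
    transversions only.
    """
    if mode not in {"all", "transition_only", "transversion_only"}:
        raise ValueError(f"unknown mode {mode!r}")
    if weighting not in {"uniform", "usage"}:
        raise ValueError(f"unknown weighting {weighting!r}")
    if weighting == "usage" and usage is None:
        raise ValueError("usage weighting requires a CodonUsageTable")

    by_aa: dict[str, list[str]] = {}
    for codon in sorted(SENSE_CODONS):
        by_aa.setdefault(CODON_TO_AA[codon], []).append(codon)

    expected: dict[str, dict[str, float]] = {}
    for aa, codons in by_aa.items():
        weights: dict[str, float] = {}
        for var in (v for c in codons for v in codon_neighbors(c)):
            if mode == "transition_only" and var.substitution != "transition":
                continue
            if mode == "transversion_only" and var.substitution != "transversion":
                continue
            if var.kind == "stop_gain" and not include_stop_gain_in_denominator:
                continue
            if var.kind == "synonymous" and not include_synonymous_in_denominator:
                continue
            w = 1.0 if weighting == "uniform" else usage.usage[var.codon]
            weights[var.to_aa] = weights.get(var.to_aa, 0.0) + w
        total = sum(weights.values())
        if total > 0:
            expected[aa] = {to: 100.0 * w / total for to, w in sorted(weights.items())}
        else:
            expected[aa] = {}
    return TheoreticalMatrix(
        mode=mode,
        weighting=weighting,
        include_stop_gain=include_stop_gain_in_denominator,
        include_synonymous=include_synonymous_in_denominator,
        expected=expected,
    )


def count_change_types(include_synonymous: bool = True, include_stop: bool = False) -> int:
    """Distinct amino-acid substitution types reachable by one substitution.

    Ordered (from, to) missense pairs among sense codons; optionally one
    synonymous self-change type per amino acid having at least one
    synonymous single-nucleotide change (all but Met and Trp); optionally
    stop-gain/stop-loss types.
    """
    missense: set[tuple[str, str]] = set()
    synonymous_self: set[str] = set()
    stop_types: set[tuple[str, str]] = set()
    for var in all_directed_changes():
        if var.kind == "missense":
            missense.add((var.from_aa, var.to_aa))
        elif var.kind == "synonymous":
            synonymous_self.add(var.from_aa)
        elif var.kind == "stop_gain":
            stop_types.add((var.from_aa, "*"))
    # stop_loss types: stop codon -> sense amino acid
    for stop in sorted(STOP_CODONS):
        for pos in range(3):
            for alt in BASES:
                if alt == stop[pos]:
                    continue
                var = stop[:pos] + alt + stop[pos + 1 :]
                aa = CODON_TO_AA[var]
                if aa != "*":
                    stop_types.add(("*", aa))
    n = len(missense)
    if include_synonymous:
        n += len(synonymous_self)
    if include_stop:
        n += len(stop_types)
    return n


def observed_aa_matrix(coding_effects) -> dict[str, dict[str, float]]:
    """Observed percent of each (from_aa -> to_aa) change, self-changes included.

    ``coding_effects`` is an iterable of objects with ``from_aa``/``to_aa``
    attributes (synonymous changes appear as from_aa == to_aa). Percentages
    are over all changes pooled.
    """
    counts: dict[tuple[str, str], int] = {}
    total = 0
    for eff in coding_effects:
        counts[(eff.from_aa, eff.to_aa)] = counts.get((eff.from_aa, eff.to_aa), 0) + 1
        total += 1
    if total == 0:
        raise ValueError("no coding effects supplied")
    out: dict[str, dict[str, float]] = {}
    for (fr, to), n in sorted(counts.items()):
        out.setdefault(fr, {})[to] = 100.0 * n / total
    return out


def normalize_rows_missense(observed: dict[str, dict[str, float]]) -> dict[str, dict[str, float]]:
    """Re-express an observed matrix on the theoretical-row convention.

    Within each source amino acid, missense targets (self-changes and stops
    dropped) are rescaled to sum to 100, making entries directly comparable
    to the default theoretical matrix.
    """
    out: dict[str, dict[str, float]] = {}
    for fr, row in observed.items():
        if fr == "*":
            continue
        targets = {to: v for to, v in row.items() if to not in {fr, "*"}}
        total = sum(targets.values())
        if total > 0:
            out[fr] = {to: 100.0 * v / total for to, v in targets.items()}
    return out


def change_type_label(from_aa: str, to_aa: str) -> str:
    """Label an amino-acid change by the nucleotide changes that realize it.

    'transition' if every single-nucleotide codon change realizing the
    amino-acid change is a transition, 'transversion' if every one is a
    transversion, 'mixed' if both occur, 'unreachable' if no single
    substitution realizes it.
    """
    kinds = {
        var.substitution
        for var in all_directed_changes()
        if var.from_aa == from_aa and var.to_aa == to_aa
    }
    if not kinds:
        return "unreachable"
    return kinds.pop() if len(kinds) == 1 else "mixed"


@dataclass
class RatioResult:
    """Observed/theoretical ratios per amino-acid change and label averages."""

    ratios: dict[tuple[str, str], float]
    labels: dict[tuple[str, str], str]
    mean_transition: float
    mean_transversion: float
    n_infinite: int

    @property
    def transition_fold_over_transversion(self) -> float:
        return self.mean_transition / self.mean_transversion


def observed_vs_theoretical(
    observed: dict[str, dict[str, float]], theoretical: TheoreticalMatrix
) -> RatioResult:
    """Per-change observed/theoretical ratios and transition/transversion means.

    Changes realizable by both a transition and a transversion are labeled
    'mixed' and excluded from the two averages; a nonzero observation with
    zero theoretical expectation yields an infinite ratio, excluded from
    the means with a log entry.
    """
    ratios: dict[tuple[str, str], float] = {}
    labels: dict[tuple[str, str], str] = {}
    n_inf = 0
    for fr, row in observed.items():
        for to, obs in row.items():
            if fr == to or to == "*" or fr == "*":
                continue  # averages are over missense types
            theo = theoretical.get(fr, to)
            key = (fr, to)
            labels[key] = change_type_label(fr, to)
            if theo == 0.0:
                ratios[key] = math.inf
                n_inf += 1
                log.warning("observed %s->%s with zero theoretical expectation", fr, to)
            else:
                ratios[key] = obs / theo
    by_label: dict[str, list[float]] = {"transition": [], "transversion": []}
    for key, r in ratios.items():
        if math.isinf(r):
            continue
        lab = labels[key]
        if lab in by_label:
            by_label[lab].append(r)
    mean = lambda xs: sum(xs) / len(xs) if xs else float("nan")
    return RatioResult(
        ratios=ratios,
        labels=labels,
        mean_transition=mean(by_label["transition"]),
        mean_transversion=mean(by_label["transversion"]),
        n_infinite=n_inf,
    )


@dataclass
class MutagenicityTable:
    """Per-codon observed-mutation frequency vs usage frequency.

    Within each amino-acid group both the observed mutated-codon counts
    and the usage frequencies are normalized to sum to 1; the ratio
    R = observed/usage exceeds 1 for codons over-mutated relative to their
    usage. ``preferred`` flags the most-used codon of each group.
    """

    rows: list[dict]  # codon, aa, usage, observed, ratio, preferred

    def ratio(self, codon: str) -> float | None:
        for row in self.rows:
            if row["codon"] == codon:
                return row["ratio"]
        raise KeyError(codon)


def mutagenicity_ratios(observed_codon_counts: dict[str, float], usage) -> MutagenicityTable:
    """Ratio of mutated-codon frequency to usage frequency, per codon.

    ``observed_codon_counts`` maps source codons (the codon carrying the
    mutation, before the change) to observed mutation counts. Amino acids
    with zero observed mutations get absent (None) ratios.
    """
    rows: list[dict] = []
    for aa in sorted(usage.by_aa):
        codons = usage.by_aa[aa]
        group_total = sum(observed_codon_counts.get(c, 0) for c in codons)
        for codon in codons:
            u = usage.usage[codon]
            if group_total > 0:
                obs = observed_codon_counts.get(codon, 0) / group_total
                ratio = obs / u if u > 0 else math.inf
            else:
                obs = None
                ratio = None
            rows.append(
                {
                    "codon": codon,
                    "aa": aa,
                    "usage": u,
                    "observed": obs,
                    "ratio": ratio,
                    "preferred": usage.preferred[aa] == codon,
                }
            )
    return MutagenicityTable(rows=rows)


def truncate2(x: float) -> float:
    """Two-decimal truncation (floor toward zero), e.g. 16.666 -> 16.66."""
    return math.trunc(x * 100) / 100
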