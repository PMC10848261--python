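"""Sequence context around mutated sites.

Windows of +/-k reference bases centered on each SNP are stacked into a
per-position composition matrix; comparing the GC fraction at the mutated
site (position 0) with the mean over flanking positions quantifies the
mutagen's base preference independent of local motifs. Windows are taken
from the reference strand without strand collapsing; a collapsed mode
(pyrimidine-centered) is available for signature-style analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reference_io import Genome, reverse_complement

BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def extract_context(genome: Genome, variant, k: int = 20, collapse_strand: bool = False) -> str:
    """2k+1 reference bases centered on a SNP; '.' marks off-contig positions.

    Positions beyond the contig edge are marked absent, never fabricated.
    With ``collapse_strand`` the window is reverse-complemented when the
    center base is a purine, so every center is a pyrimidine.
    """
    if not variant.is_snp:
        raise ValueError("context extraction is defined for SNPs only")
    seq = genome.contigs.get(variant.contig)
    if seq is None:
        raise KeyError(f"contig {variant.contig!r} not in genome")
    n = len(seq)
    pos0 = variant.pos - 1
    if not 0 <= pos0 < n:
        raise ValueError(f"position {variant.pos} off contig {variant.contig} (len {n})")
    lo, hi = pos0 - k, pos0 + k + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - n)
    window = "." * left_pad + seq[max(0, lo) : min(n, hi)] + "." * right_pad
    if collapse_strand and window[k] in "AG":
        window = reverse_complement(window.replace(".", "N")).replace("N", ".")
    return window


@dataclass
class CompositionMatrix:
    """Per-position base counts over a stack of equal-width windows."""

    k: int
    counts: np.ndarray  # (2k+1, 4) counts of A,C,G,T
    denominators: np.ndarray  # (2k+1,) valid bases per position

    @property
    def positions(self) -> np.ndarray:
        return np.arange(-self.k, self.k + 1)

    @property
    def fractions(self) -> np.ndarray:
        """(2k+1, 4) per-position base fractions over counted bases."""
        denom = self.denominators[:, None].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, self.counts / denom, np.nan)

    @property
    def gc_fraction(self) -> np.ndarray:
        """Per-position G+C fraction."""
        f = self.fractions
        return f[:, BASE_INDEX["G"]] + f[:, BASE_INDEX["C"]]


def composition_matrix(windows: list[str]) -> CompositionMatrix:
    """Stack windows into per-position A/C/G/T counts.

    Absent ('.') and N bases are excluded from a position's denominator,
    so interior positions have denominator n_windows and positions near
    contig edges have smaller ones.
    """
    if not windows:
        raise ValueError("no windows supplied")
    width = len(windows[0])
    if width % 2 != 1 or any(len(w) != width for w in windows):
        raise ValueError("windows must share an odd width 2k+1")
    k = width // 2
    counts = np.zeros((width, 4), dtype=np.int64)
    denom = np.zeros(width, dtype=np.int64)
    for w in windows:
        for i, base in enumerate(w):
            j = BASE_INDEX.get(base)
            if j is not None:
                counts[i, j] += 1
                denom[i] += 1
    return CompositionMatrix(k=k, counts=counts, denominators=denom)


def site_vs_flank_gc(matrix: CompositionMatrix) -> dict[str, float]:
    """GC percent at the mutated site vs the mean over flanking positions."""
    gc = matrix.gc_fraction
    site = gc[matrix.k]
    flank = np.nanmean(np.delete(gc, matrix.k))
    return {"site_gc_percent": 100.0 * site, "flank_gc_percent": 100.0 * float(flank)}


def write_composition_tsv(matrix: CompositionMatrix, path) -> None:
    frac = matrix.fractions
    with open(path, "w") as fh:
        fh.write("position\tA\tC\tG\tT\tn\n")
        for row, pos in enumerate(matrix.positions):
            vals = "\t".join(f"{frac[row, j]:.6f}" for j in range(4))
            fh.write(f"{pos}\t{vals}\t{matrix.denominators[row]}\n")
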