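"""Variant records, VCF I/O, hard filtering and parental subtraction.

Variant identity for all set algebra is the allele key
(contig, pos, ref, alt); zygosity never distinguishes variants, matching
how parental calls are subtracted by site and allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import pysam

log = logging.getLogger(__name__)

FILTER_KEYS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")

#: GATK-style hard-filter thresholds. A record is removed when any present
#: annotation crosses its threshold; an absent annotation passes.
SNP_FILTERS = {
    "QD": ("<", 2.0),
    "FS": (">", 60.0),
    "MQ": ("<", 40.0),
    "MQRankSum": ("<", -12.5),
    "ReadPosRankSum": ("<", -8.0),
}
INDEL_FILTERS = {
    "QD": ("<", 2.0),
    "FS": (">", 200.0),
    "ReadPosRankSum": ("<", -20.0),
}


@dataclass(frozen=True)
class Variant:
    """One substitution or InDel call from one mutant line."""

    line_id: str
    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    zygosity: str = "unknown"  # het | hom | unknown
    filter_fields: dict | None = None
    sift_score: float | None = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.contig}:{self.pos}")
        if len(self.ref) > 1 and len(self.alt) > 1 and len(self.ref) == len(self.alt):
            raise ValueError(
                f"MNP at {self.contig}:{self.pos} ({self.ref}>{self.alt}): "
                "only SNPs and short InDels are supported"
            )
        if self.sift_score is not None and not 0.0 <= self.sift_score <= 1.0:
            raise ValueError(f"SIFT score {self.sift_score} outside [0,1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def kind(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNP"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def is_snp(self) -> bool:
        return self.kind == "SNP"


class VariantSet:
    """Per-line variant collection keyed by (contig, pos, ref, alt)."""

    def __init__(self, line_id: str, variants: list[Variant] | None = None):
        self.line_id = line_id
        self._by_key: dict[tuple, Variant] = {}
        for v in variants or []:
            self.add(v)

    def add(self, v: Variant) -> None:
        if v.key in self._by_key:
            raise ValueError(f"duplicate variant key {v.key} in line {self.line_id}")
        self._by_key[v.key] = v

    def __len__(self) -> int:
        return len(self._by_key)

    def __contains__(self, key) -> bool:
        return key in self._by_key

    def __iter__(self) -> Iterator[Variant]:
        yield from sorted(self._by_key.values(), key=lambda v: (v.contig, v.pos, v.ref, v.alt))

    @property
    def keys(self) -> set[tuple]:
        return set(self._by_key)

    def get(self, key) -> Variant | None:
        return self._by_key.get(key)

    def snps(self) -> list[Variant]:
        return [v for v in self if v.is_snp]

    def indels(self) -> list[Variant]:
        return [v for v in self if not v.is_snp]


def _zygosity_from_gt(gt: tuple) -> str:
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return "unknown"
    non_ref = [a for a in alleles if a and a > 0]
    if not non_ref:
        return "unknown"
    return "hom" if len(alleles) >= 2 and all(a == alleles[0] for a in alleles) else "het"


def read_vcf(path: str | Path, line_id: str | None = None) -> VariantSet:
    """Read a (plain or bgzipped) VCF into a VariantSet.

    Multi-allelic records are split into one Variant per alternate allele;
    zygosity comes from the first sample's GT (0/1 -> het, 1/1 -> hom,
    ./. -> unknown).
    """
    if line_id is None:
        line_id = Path(path).stem.replace(".vcf", "")
    vs = VariantSet(line_id)
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = {k: rec.info[k] for k in FILTER_KEYS if k in rec.info}
            zyg = "unknown"
            if rec.samples:
                sample = rec.samples[0]
                gt = sample.get("GT")
                if gt is not None:
                    zyg = _zygosity_from_gt(gt)
            for alt in rec.alts or ():
                if alt is None or alt in {".", "*", "<NON_REF>"}:
                    continue
                vs.add(
                    Variant(
                        line_id=line_id,
                        contig=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        zygosity=zyg,
                        filter_fields=info or None,
                    )
                )
    return vs


def write_vcf(variants: VariantSet, path: str | Path, contig_lengths: dict[str, int]) -> None:
    """Write a VariantSet as VCF v4.2 with GT and any hard-filter INFO fields."""
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    for key in FILTER_KEYS:
        header.info.add(key, 1, "Float", f"{key} annotation")
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(variants.line_id)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.contig, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            for k, val in (v.filter_fields or {}).items():
                rec.info[k] = val
            gt = {"hom": (1, 1), "het": (0, 1), "unknown": (None, None)}[v.zygosity]
            rec.samples[variants.line_id]["GT"] = gt
            out.write(rec)


def _fails(fields: dict | None, thresholds: dict) -> bool:
    if not fields:
        return False
    for key, (op, cut) in thresholds.items():
        if key not in fields or fields[key] is None:
            continue  # absent annotation passes the criterion
        val = float(fields[key])
        if (op == "<" and val < cut) or (op == ">" and val > cut):
            return True
    return False


def apply_hard_filters(variants: VariantSet) -> VariantSet:
    """Remove records failing the hard-filter thresholds.

    SNPs fail on QD<2, FS>60, MQ<40, MQRankSum<-12.5 or
    ReadPosRankSum<-8; InDels on QD<2, FS>200 or ReadPosRankSum<-20.
    Absent annotations pass their criterion. Idempotent.
    """
    kept, dropped = [], 0
    for v in variants:
        thresholds = SNP_FILTERS if v.is_snp else INDEL_FILTERS
        if _fails(v.filter_fields, thresholds):
            dropped += 1
        else:
            kept.append(v)
    log.info("hard filters: line %s kept %d, removed %d", variants.line_id, len(kept), dropped)
    return VariantSet(variants.line_id, kept)


def subtract_parental(line_set: VariantSet, parental_set: VariantSet) -> VariantSet:
    """Remove every allele present in the parental cultivar's call set."""
    kept = [v for v in line_set if v.key not in parental_set]
    return VariantSet(line_set.line_id, kept)


def read_sift_table(path: str | Path) -> dict[tuple, float]:
    """TSV ``contig pos ref alt gene score`` -> {(contig,pos,ref,alt): score}."""
    table: dict[tuple, float] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if i == 0 and parts[0].lower() in {"contig", "chrom"}:
                continue
            contig, pos, ref, alt = parts[0], int(parts[1]), parts[2], parts[3]
            score = float(parts[5] if len(parts) > 5 else parts[4])
            table[(contig, pos, ref, alt)] = score
    return table


def attach_sift(variants: VariantSet, sift_table: dict[tuple, float]) -> VariantSet:
    """Attach SIFT scores by allele key; unmatched variants stay unscored."""
    for score in sift_table.values():
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"SIFT score {score} outside [0,1]")
    out = []
    for v in variants:
        score = sift_table.get(v.key)
        out.append(replace(v, sift_score=score) if score is not None else v)
    return VariantSet(variants.line_id, out)


TABLE_COLUMNS = ["line_id", "contig", "pos", "ref", "alt", "kind", "zygosity", "sift_score"]


def write_variant_table(variants: VariantSet, path: str | Path) -> None:
    """Lossless TSV export with a stable column order."""
    with open(path, "w") as fh:
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for v in variants:
            sift = "" if v.sift_score is None else f"{v.sift_score:.4f}"
            fh.write(
                f"{v.line_id}\t{v.contig}\t{v.pos}\t{v.ref}\t{v.alt}\t"
                f"{v.kind}\t{v.zygosity}\t{sift}\n"
            )


def read_variant_table(path: str | Path) -> VariantSet:
    variants = []
    line_id = "unknown"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for row in fh:
            parts = row.rstrip("\n").split("\t")
            line_id = parts[idx["line_id"]]
            sift = parts[idx["sift_score"]]
            variants.append(
                Variant(
                    line_id=line_id,
                    contig=parts[idx["contig"]],
                    pos=int(parts[idx["pos"]]),
                    ref=parts[idx["ref"]],
                    alt=parts[idx["alt"]],
                    zygosity=parts[idx["zygosity"]],
                    sift_score=float(sift) if sift else None,
                )
            )
    return VariantSet(line_id, variants)
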