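"""Data model and I/O for multi-sample genotype data, interval masks and pedigrees.

Coordinate conventions: VCF positions are 1-based; BED files and every
in-memory interval are 0-based half-open. Conversion happens only at the I/O
boundary (``load_sites`` / ``write_vcf``).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Pedigree",
    "GenotypeCall",
    "SiteRecord",
    "IntervalSet",
    "classify_site",
    "minor_allele_balance",
    "load_pedigree",
    "write_pedigree",
    "load_intervals",
    "load_sites",
    "write_vcf",
    "MONOMORPHIC",
    "BIALLELIC_SNP",
    "OTHER",
]

MONOMORPHIC = "monomorphic"
BIALLELIC_SNP = "biallelic_snp"
OTHER = "other"

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class Pedigree:
    """A two-parent pedigree with one or more offspring (one trio per offspring)."""

    mother_id: str
    father_id: str
    offspring_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        offspring = tuple(self.offspring_ids)
        object.__setattr__(self, "offspring_ids", offspring)
        if not offspring:
            raise ValueError("pedigree needs at least one offspring")
        ids = [self.mother_id, self.father_id, *offspring]
        if len(set(ids)) != len(ids):
            raise ValueError(f"pedigree sample identifiers are not distinct: {ids}")

    @property
    def samples(self) -> tuple[str, ...]:
        """All sample ids, parents first."""
        return (self.mother_id, self.father_id, *self.offspring_ids)

    def trios(self) -> list[tuple[str, str, str]]:
        """(mother, father, focal offspring) triples, one per offspring."""
        return [(self.mother_id, self.father_id, o) for o in self.offspring_ids]


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at one site.

    ``allele_depths`` is aligned with the site's allele list (ref first).
    A missing call has ``alleles`` set to None; quality fields may then be
    absent too.
    """

    alleles: tuple[str, str] | None
    allele_depths: tuple[int, ...] | None = None
    total_depth: int | None = None
    gq: float | None = None

    def __post_init__(self) -> None:
        if self.allele_depths is not None:
            if any(d < 0 for d in self.allele_depths):
                raise ValueError("negative allele depth")
            if self.total_depth is not None and sum(self.allele_depths) > self.total_depth:
                raise ValueError(
                    f"allele depths {self.allele_depths} exceed total depth {self.total_depth}"
                )

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def is_het(self) -> bool:
        return self.alleles is not None and self.alleles[0] != self.alleles[1]

    @property
    def is_hom(self) -> bool:
        return self.alleles is not None and self.alleles[0] == self.alleles[1]


def minor_allele_balance(call: GenotypeCall) -> float | None:
    """Minor allele balance over the two site-defining alleles.

    min(AD) / sum(AD) computed on the first two allele-depth entries (the ref
    and the single alt of a biallelic site); reads supporting other alleles do
    not enter the balance (they still count toward total depth). Returns None
    when the balance is undefined (no reads on the site alleles, or no AD),
    which downstream filters treat as a failure.
    """
    if call.allele_depths is None:
        return None
    depths = call.allele_depths[:2]
    total = sum(depths)
    if total == 0:
        return None
    if len(depths) == 1:
        return 0.0
    return min(depths) / total


def classify_site(record: "SiteRecord") -> str:
    """monomorphic (no alt), biallelic_snp (one single-base alt), or other."""
    alts = record.alt_alleles
    if len(alts) == 0:
        return MONOMORPHIC
    if (
        len(alts) == 1
        and len(record.ref_allele) == 1
        and len(alts[0]) == 1
        and record.ref_allele in _BASES
        and alts[0] in _BASES
    ):
        return BIALLELIC_SNP
    return OTHER


@dataclass
class SiteRecord:
    """One genomic position: per-sample calls plus site-level annotations.

    ``position`` is 1-based (VCF convention). Annotation fields are None when
    the caller did not emit them; absence is not evidence of low quality and
    the corresponding filters pass (see callability).
    """

    contig: str
    position: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    calls: dict[str, GenotypeCall]
    mapping_quality: float | None = None
    quality_by_depth: float | None = None
    base_quality_rank_sum: float | None = None
    read_position_rank_sum: float | None = None

    @property
    def site_class(self) -> str:
        return classify_site(self)

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref_allele, *self.alt_alleles)


class IntervalSet:
    """Per-contig sorted, disjoint, 0-based half-open intervals.

    Intervals are merged on construction; ``start >= end`` is fatal.
    """

    def __init__(self, intervals: Mapping[str, Sequence[tuple[int, int]]] | None = None):
        self._data: dict[str, np.ndarray] = {}
        if intervals:
            for contig, pairs in intervals.items():
                self._set_contig(contig, pairs)

    def _set_contig(self, contig: str, pairs: Sequence[tuple[int, int]]) -> None:
        arr = np.asarray(sorted((int(s), int(e)) for s, e in pairs), dtype=np.int64)
        if arr.size == 0:
            return
        if np.any(arr[:, 0] >= arr[:, 1]):
            bad = arr[arr[:, 0] >= arr[:, 1]][0]
            raise ValueError(f"invalid interval {contig}:{bad[0]}-{bad[1]} (start >= end)")
        if np.any(arr[:, 0] < 0):
            raise ValueError(f"negative interval start on {contig}")
        merged: list[list[int]] = []
        for s, e in arr:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        self._data[contig] = np.asarray(merged, dtype=np.int64)

    @classmethod
    def from_pairs(cls, triples: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in triples:
            by_contig.setdefault(contig, []).append((start, end))
        return cls(by_contig)

    @property
    def contigs(self) -> list[str]:
        return sorted(self._data)

    def intervals(self, contig: str) -> np.ndarray:
        """(n, 2) array of [start, end) pairs for one contig (empty if absent)."""
        return self._data.get(contig, np.empty((0, 2), dtype=np.int64))

    def is_empty(self) -> bool:
        return not self._data

    def total_bases(self) -> int:
        return int(sum((arr[:, 1] - arr[:, 0]).sum() for arr in self._data.values()))

    def contains(self, contig: str, pos: int) -> bool:
        """Membership of a single 0-based position."""
        return bool(self.contains_positions(contig, np.asarray([pos]))[0])

    def contains_positions(self, contig: str, positions: np.ndarray) -> np.ndarray:
        """Vectorised membership for an array of 0-based positions."""
        positions = np.asarray(positions, dtype=np.int64)
        arr = self._data.get(contig)
        if arr is None or arr.size == 0:
            return np.zeros(positions.shape, dtype=bool)
        idx = np.searchsorted(arr[:, 0], positions, side="right") - 1
        inside = idx >= 0
        inside[inside] = positions[inside] < arr[idx[inside], 1]
        return inside

    def mask_array(self, contig: str, length: int) -> np.ndarray:
        """Boolean mask of length ``length`` (True inside an interval)."""
        mask = np.zeros(length, dtype=bool)
        for s, e in self.intervals(contig):
            mask[s:min(e, length)] = True
        return mask

    def union(self, other: "IntervalSet") -> "IntervalSet":
        pairs: list[tuple[str, int, int]] = []
        for iset in (self, other):
            for contig in iset.contigs:
                for s, e in iset.intervals(contig):
                    pairs.append((contig, int(s), int(e)))
        return IntervalSet.from_pairs(pairs)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for contig in self.contigs:
                for s, e in self.intervals(contig):
                    fh.write(f"{contig}\t{s}\t{e}\n")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if self.contigs != other.contigs:
            return False
        return all(
            np.array_equal(self.intervals(c), other.intervals(c)) for c in self.contigs
        )

    def __repr__(self) -> str:
        n = sum(len(a) for a in self._data.values())
        return f"IntervalSet({len(self._data)} contigs, {n} intervals, {self.total_bases()} bases)"


def load_intervals(bed_source: str | Path) -> IntervalSet:
    """Read a 3+-column BED (0-based half-open) into a merged IntervalSet."""
    triples: list[tuple[str, int, int]] = []
    with open(bed_source) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{bed_source}:{lineno}: fewer than 3 BED columns")
            triples.append((parts[0], int(parts[1]), int(parts[2])))
    return IntervalSet.from_pairs(triples)


_ROLES = {"mother", "father", "offspring"}


def load_pedigree(path: str | Path) -> Pedigree:
    """Read a tab-separated pedigree file (columns: sample_id, role)."""
    mother: str | None = None
    father: str | None = None
    offspring: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or parts[1] not in _ROLES:
                raise ValueError(f"{path}:{lineno}: expected 'sample_id<TAB>role'")
            sample, role = parts[0], parts[1]
            if role == "mother":
                if mother is not None:
                    raise ValueError(f"{path}: more than one mother")
                mother = sample
            elif role == "father":
                if father is not None:
                    raise ValueError(f"{path}: more than one father")
                father = sample
            else:
                offspring.append(sample)
    if mother is None or father is None:
        raise ValueError(f"{path}: pedigree must name one mother and one father")
    return Pedigree(mother, father, tuple(offspring))


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{pedigree.mother_id}\tmother\n")
        fh.write(f"{pedigree.father_id}\tfather\n")
        for o in pedigree.offspring_ids:
            fh.write(f"{o}\toffspring\n")


def _fmt_float(x: float) -> str:
    return format(float(x), ".6g")


def load_sites(vcf_source: str | Path, pedigree: Pedigree) -> Iterator[SiteRecord]:
    """Stream SiteRecords from a multi-sample VCF, in coordinate order.

    Requires GT/AD/DP/GQ in FORMAT for the pedigree samples. Missing
    annotations surface as None, never as defaults. A pedigree sample absent
    from the header, or a malformed record, is fatal.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_source), gts012=False)
    header_samples = list(vcf.samples)
    missing = [s for s in pedigree.samples if s not in header_samples]
    if missing:
        raise ValueError(f"pedigree samples absent from VCF header: {missing}")
    idx = {s: header_samples.index(s) for s in pedigree.samples}

    for variant in vcf:
        try:
            yield _record_from_variant(variant, pedigree, idx)
        except Exception as exc:  # pragma: no cover - defensive re-raise with locus
            raise ValueError(
                f"malformed VCF record at {variant.CHROM}:{variant.POS}: {exc}"
            ) from exc


def _info_float(variant, key: str) -> float | None:
    val = variant.INFO.get(key)
    if val is None:
        return None
    return float(val)


def _record_from_variant(variant, pedigree: Pedigree, idx: dict[str, int]) -> SiteRecord:
    ref = variant.REF
    alts = tuple(a for a in (variant.ALT or []) if a != ".")
    alleles = (ref, *alts)

    ad = variant.format("AD")
    dp = variant.format("DP")
    gq = variant.format("GQ")
    gts = variant.genotypes

    calls: dict[str, GenotypeCall] = {}
    for sample in pedigree.samples:
        i = idx[sample]
        g = gts[i]
        a, b = int(g[0]), int(g[1])
        sample_dp = None
        if dp is not None and dp[i][0] >= 0:
            sample_dp = int(dp[i][0])
        sample_gq = None
        if gq is not None:
            v = float(np.asarray(gq[i]).ravel()[0])
            if v >= 0:
                sample_gq = v
        sample_ad: tuple[int, ...] | None = None
        if ad is not None:
            row = np.asarray(ad[i]).ravel()
            if row.size and row[0] >= 0:
                sample_ad = tuple(int(x) for x in row[: len(alleles)])
        if a < 0 or b < 0:
            calls[sample] = GenotypeCall(None, sample_ad, sample_dp, sample_gq)
        else:
            calls[sample] = GenotypeCall(
                (alleles[a], alleles[b]), sample_ad, sample_dp, sample_gq
            )

    return SiteRecord(
        contig=variant.CHROM,
        position=int(variant.POS),
        ref_allele=ref,
        alt_alleles=alts,
        calls=calls,
        mapping_quality=_info_float(variant, "MQ"),
        quality_by_depth=_info_float(variant, "QD"),
        base_quality_rank_sum=_info_float(variant, "BaseQRankSum"),
        read_position_rank_sum=_info_float(variant, "ReadPosRankSum"),
    )


_VCF_HEADER_LINES = [
    '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth">',
    '##INFO=<ID=BaseQRankSum,Number=1,Type=Float,Description="Base quality rank sum">',
    '##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
]


def write_vcf(
    records: Iterable[SiteRecord],
    samples: Sequence[str],
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write SiteRecords to a plain-text VCF (v4.2).

    Annotation floats are rendered with 6 significant digits, which
    round-trips through cyvcf2's float parsing at that precision.
    """
    records = list(records)
    if contig_lengths is None:
        contig_lengths = {}
        for r in records:
            contig_lengths[r.contig] = max(contig_lengths.get(r.contig, 0), r.position)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=dnmpipe\n")
        for contig, length in contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t")
        fh.write("FORMAT\t" + "\t".join(samples) + "\n")
        for rec in records:
            fh.write(_format_vcf_row(rec, samples) + "\n")


def _format_vcf_row(rec: SiteRecord, samples: Sequence[str]) -> str:
    alt_field = ",".join(rec.alt_alleles) if rec.alt_alleles else "."
    info_parts = []
    for key, val in (
        ("MQ", rec.mapping_quality),
        ("QD", rec.quality_by_depth),
        ("BaseQRankSum", rec.base_quality_rank_sum),
        ("ReadPosRankSum", rec.read_position_rank_sum),
    ):
        if val is not None:
            info_parts.append(f"{key}={_fmt_float(val)}")
    info = ";".join(info_parts) if info_parts else "."
    allele_index = {a: i for i, a in enumerate(rec.alleles)}
    cols = [rec.contig, str(rec.position), ".", rec.ref_allele, alt_field, ".", "PASS", info,
            "GT:AD:DP:GQ"]
    for sample in samples:
        call = rec.calls.get(sample)
        if call is None or call.is_missing:
            gt = "./."
        else:
            gt = "/".join(str(allele_index[a]) for a in sorted(call.alleles, key=allele_index.get))
        ad = ",".join(str(d) for d in call.allele_depths) if call and call.allele_depths else "."
        dp = str(call.total_depth) if call and call.total_depth is not None else "."
        gqs = str(int(round(call.gq))) if call and call.gq is not None else "."
        cols.append(f"{gt}:{ad}:{dp}:{gqs}")
    return "\t".join(cols)
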