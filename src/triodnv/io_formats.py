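"""Readers and writers for the file formats shared by every pipeline stage.

Coordinate conventions
----------------------
All in-memory intervals are 0-based half-open ``[start, end)``.  Everything
VCF-facing (``TrioGenotypeRecord.pos``, read-evidence positions) is 1-based,
as in the file format.  Converting between the two twice is the identity.

Structural-variant lengths follow the HGVS reporting convention used for
genomic deletions (``g.<first>_<last>del<n>`` counts both end bases), so the
canonical ``SvCall.length`` for DEL/DUP/INV equals ``span + 1`` where
``span = end - start`` is the half-open interval width.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from cyvcf2 import VCF

log = logging.getLogger(__name__)

TRIO_MEMBERS = ("child", "father", "mother")
SV_TYPES = ("DEL", "DUP", "INS", "INV")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A labelled genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    label: str = ""
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"end <= start: {self}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def span(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class TrioGenotypeRecord:
    """One biallelic site with child/father/mother genotypes.

    ``pos`` is the 1-based VCF position.  Genotypes are tuples of allele
    indices in {0, 1} (``None`` when the member's genotype is missing);
    ``allele_depths`` maps member -> (ref_depth, alt_depth); ``qualities``
    holds the phred-scale genotype-posterior quality per member.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: dict
    allele_depths: dict = field(default_factory=dict)
    qualities: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.alt == self.ref:
            raise ValueError(f"alt == ref at {self.chrom}:{self.pos}")
        for member, gt in self.genotypes.items():
            if gt is not None and any(a not in (0, 1) for a in gt):
                raise ValueError(f"non-biallelic genotype {gt} for {member}")
        for member, ad in self.allele_depths.items():
            if ad is not None and (ad[0] < 0 or ad[1] < 0):
                raise ValueError(f"negative depth for {member}")


@dataclass(frozen=True)
class Pedigree:
    """One trio family: sample ids plus parental ages at conception."""

    family_id: str
    child_id: str
    father_id: str
    mother_id: str
    child_sex: str = "unknown"
    father_age: float | None = None
    mother_age: float | None = None

    def __post_init__(self):
        ids = {self.child_id, self.father_id, self.mother_id}
        if len(ids) != 3:
            raise ValueError(f"trio sample ids not distinct in {self.family_id}")
        for age in (self.father_age, self.mother_age):
            if age is not None and age <= 0:
                raise ValueError(f"non-positive age in {self.family_id}")


@dataclass
class ReadEvidence:
    """Alleles observed on one read (or read pair) of one sample.

    ``observations`` is a list of ``(1-based position, allele string)``
    pairs, strictly increasing in position.
    """

    read_id: str
    sample_id: str
    observations: list

    def __post_init__(self):
        positions = [p for p, _ in self.observations]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError(f"positions not strictly increasing in read {self.read_id}")

    def allele_at(self, pos: int):
        for p, a in self.observations:
            if p == pos:
                return a
        return None


@dataclass
class SvCall:
    """A structural-variant call from one caller for one sample."""

    chrom: str
    start: int
    end: int
    svtype: str
    length: int
    caller: str
    sample: str
    status: str = "called"

    def __post_init__(self):
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.svtype!r}")
        if self.status not in ("called", "candidate"):
            raise ValueError(f"bad status {self.status!r}")
        if self.end <= self.start:
            raise ValueError(f"end <= start in SV {self.chrom}:{self.start}-{self.end}")
        if self.svtype in ("DEL", "DUP", "INV") and self.length != self.span + 1:
            raise ValueError(
                f"length {self.length} inconsistent with span {self.span} "
                f"for {self.svtype} (expected span + 1)"
            )

    @property
    def span(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# trio VCF
# ---------------------------------------------------------------------------

def _decompose_site(variant, sample_idx: dict, alt_index: int):
    """Build one TrioGenotypeRecord for ALT allele ``alt_index`` (0-based)."""
    want = alt_index + 1
    genotypes, depths, quals = {}, {}, {}
    gts = variant.genotypes
    try:
        ad = variant.format("AD")
    except KeyError:
        ad = None
    gq = variant.gt_quals
    for member, i in sample_idx.items():
        alleles = gts[i][:-1]
        if any(a < 0 for a in alleles):
            genotypes[member] = None
        else:
            genotypes[member] = tuple(sorted(1 if a == want else 0 for a in alleles))
        if ad is not None and ad[i][0] >= 0:
            row = ad[i]
            alt_d = int(row[want]) if len(row) > want and row[want] >= 0 else 0
            depths[member] = (int(row[0]), alt_d)
        else:
            depths[member] = None
        quals[member] = float(gq[i]) if gq is not None and gq[i] >= 0 else None
    return TrioGenotypeRecord(
        chrom=variant.CHROM,
        pos=variant.POS,
        ref=variant.REF,
        alt=variant.ALT[alt_index],
        genotypes=genotypes,
        allele_depths=depths,
        qualities=quals,
    )


def read_trio_vcf(
    path: str | Path,
    pedigree: Pedigree,
    decompose_multiallelic: bool = True,
) -> list[TrioGenotypeRecord]:
    """Read a multi-sample VCF into per-site trio genotype records.

    Multiallelic sites are decomposed into one biallelic record per ALT
    allele by default (``decompose_multiallelic=False`` skips them
    instead).  Raises ``ValueError`` naming any pedigree sample missing
    from the VCF header.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    wanted = {
        "child": pedigree.child_id,
        "father": pedigree.father_id,
        "mother": pedigree.mother_id,
    }
    sample_idx = {}
    for member, sid in wanted.items():
        if sid not in samples:
            raise ValueError(f"sample not found in VCF header: {sid}")
        sample_idx[member] = samples.index(sid)

    records = []
    for variant in vcf:
        if not variant.ALT:
            continue
        n_alt = len(variant.ALT)
        if n_alt > 1 and not decompose_multiallelic:
            log.warning("skipping multiallelic site %s:%d", variant.CHROM, variant.POS)
            continue
        for k in range(n_alt):
            try:
                records.append(_decompose_site(variant, sample_idx, k))
            except ValueError as exc:
                log.warning("skipping malformed genotype at %s:%d (%s)",
                            variant.CHROM, variant.POS, exc)
    return records


_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype posterior quality (phred)">
"""


def write_trio_vcf(
    path: str | Path,
    records: Sequence[TrioGenotypeRecord],
    pedigree: Pedigree,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write trio genotype records as a three-sample VCF (text, uncompressed)."""
    sample_ids = (pedigree.child_id, pedigree.father_id, pedigree.mother_id)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.alt)):
            cols = [rec.chrom, str(rec.pos), ".", rec.ref, rec.alt, ".", "PASS", ".",
                    "GT:AD:GQ"]
            for member in TRIO_MEMBERS:
                gt = rec.genotypes.get(member)
                gt_s = "./." if gt is None else f"{gt[0]}/{gt[1]}"
                ad = rec.allele_depths.get(member)
                ad_s = "." if ad is None else f"{ad[0]},{ad[1]}"
                gq = rec.qualities.get(member)
                gq_s = "." if gq is None else str(int(round(gq)))
                cols.append(f"{gt_s}:{ad_s}:{gq_s}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# BED tracks
# ---------------------------------------------------------------------------

def read_bed_track(path: str | Path, label: str = "") -> list[GenomicInterval]:
    """Read a BED3+ file into sorted intervals.

    Column 4 is used as the interval label when present, otherwise
    ``label``.  Column 6 supplies the strand when present.  Raises
    ``ValueError`` (with the line number) on ``end <= start``.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start ({start}, {end})")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else label
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            intervals.append(GenomicInterval(chrom, start, end, name, strand))
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

_PED_COLUMNS = ["family_id", "child_id", "father_id", "mother_id",
                "child_sex", "father_age", "mother_age"]


def read_pedigree(path: str | Path) -> list[Pedigree]:
    """Read the extended pedigree TSV (PED-like plus two age columns)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_PED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pedigree file missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(Pedigree(
            family_id=str(row.family_id),
            child_id=str(row.child_id),
            father_id=str(row.father_id),
            mother_id=str(row.mother_id),
            child_sex=str(row.child_sex),
            father_age=None if pd.isna(row.father_age) else float(row.father_age),
            mother_age=None if pd.isna(row.mother_age) else float(row.mother_age),
        ))
    return out


def write_pedigree(pedigrees: Iterable[Pedigree], path: str | Path) -> None:
    rows = [[p.family_id, p.child_id, p.father_id, p.mother_id,
             p.child_sex, p.father_age, p.mother_age] for p in pedigrees]
    pd.DataFrame(rows, columns=_PED_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# read evidence (simplified tabular dialect; canonical for tests)
# ---------------------------------------------------------------------------

def read_evidence_tsv(path: str | Path) -> list[ReadEvidence]:
    """Read the read-evidence TSV: read_id, sample_id, ``pos:allele`` pairs."""
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ValueError(f"{path}: expected header starting with 'read_id'")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            read_id, sample_id, obs_s = line.split("\t")
            obs = []
            for pair in obs_s.split(","):
                pos_s, allele = pair.split(":")
                obs.append((int(pos_s), allele))
            out.append(ReadEvidence(read_id, sample_id, obs))
    return out


def write_evidence_tsv(evidence: Iterable[ReadEvidence], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tsample_id\tobservations\n")
        for ev in evidence:
            obs_s = ",".join(f"{p}:{a}" for p, a in ev.observations)
            fh.write(f"{ev.read_id}\t{ev.sample_id}\t{obs_s}\n")


# ---------------------------------------------------------------------------
# SV VCF
# ---------------------------------------------------------------------------

def read_sv_vcf(
    path: str | Path,
    caller_id: str,
    status: str = "called",
    sample_id: str | None = None,
) -> list[SvCall]:
    """Read an SV VCF (Manta/FermiKit-style) into ``SvCall`` records.

    POS/END are converted from 1-based VCF to the internal 0-based
    half-open interval ``[POS - 1, END)``; the canonical length for
    DEL/DUP/INV is ``span + 1`` (HGVS deletion-length convention).
    Records without a resolvable END or SVLEN, and unsupported types
    (e.g. BND), are skipped with a warning.
    """
    vcf = VCF(str(path))
    sample = sample_id or (vcf.samples[0] if vcf.samples else "unknown")
    calls = []
    for variant in vcf:
        svtype = variant.INFO.get("SVTYPE")
        if svtype is None and variant.ALT and variant.ALT[0].startswith("<"):
            svtype = variant.ALT[0].strip("<>")
        if svtype not in SV_TYPES:
            log.warning("skipping unsupported SV type %r at %s:%d",
                        svtype, variant.CHROM, variant.POS)
            continue
        start = variant.POS - 1
        end_info = variant.INFO.get("END")
        svlen = variant.INFO.get("SVLEN")
        if isinstance(svlen, (tuple, list)):
            svlen = svlen[0]
        if svtype == "INS":
            if svlen is None:
                log.warning("skipping INS without SVLEN at %s:%d",
                            variant.CHROM, variant.POS)
                continue
            end = start + 1
            length = abs(int(svlen))
        else:
            if end_info is not None:
                end = int(end_info)
            elif svlen is not None:
                end = start + abs(int(svlen))
            else:
                log.warning("skipping SV without END/SVLEN at %s:%d",
                            variant.CHROM, variant.POS)
                continue
            length = (end - start) + 1
        # non-PASS records are low-confidence candidate-level calls
        rec_status = status if variant.FILTER is None else "candidate"
        calls.append(SvCall(variant.CHROM, start, end, svtype, length,
                            caller=caller_id, sample=sample, status=rec_status))
    return calls


def write_sv_vcf(
    calls: Sequence[SvCall],
    path: str | Path,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write SV calls as a minimal symbolic-allele SV VCF."""
    sample = calls[0].sample if calls else "sample"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End (1-based)">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##FILTER=<ID=LowQual,Description="Candidate-level record">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for c in sorted(calls, key=lambda x: (x.chrom, x.start)):
            info = f"SVTYPE={c.svtype};END={c.end};SVLEN={c.length}"
            filt = "PASS" if c.status == "called" else "LowQual"
            fh.write(f"{c.chrom}\t{c.start + 1}\t.\tN\t<{c.svtype}>\t.\t{filt}\t{info}"
                     f"\tGT\t0/1\n")


# ---------------------------------------------------------------------------
# reference sequence
# ---------------------------------------------------------------------------

def load_reference(path: str | Path):
    """Open a FASTA reference for random access (pyfaidx)."""
    from pyfaidx import Fasta
    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


def fetch_sequence(reference, chrom: str, start: int, end: int) -> str:
    """Fetch ``[start, end)`` from a pyfaidx Fasta or a plain dict of strings."""
    seq = reference[chrom][start:end]
    return str(seq).upper()


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
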