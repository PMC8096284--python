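"""Readers and writers for the formats the genotyper touches.

FASTA references are loaded through pyfaidx; SV sets come in as BED4+
(``chrom start end svtype[;id][;seq=...]``, 0-based half-open) or VCF 4.2
(1-based POS, symbolic ``<DEL>``/``<INV>``/``<INS>`` with INFO END, or
literal REF/ALT indels).  Reads are streamed from FASTQ/FASTA (plain or
gzip) or from SAM/BAM treated purely as a read stream — the alignment is
ignored, only the stored sequence is used, which is safe because
counting is canonical.  The extracted k-mer panel is a versioned
tab-separated file designed to round-trip bit-exactly.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pysam

from .extraction import CONTROL_SV_ID, KmerProfile, Panel
from .genotyping import GenotypeCall
from .kmers import canonical, decode_kmer, encode_kmer, seqs_to_matrix
from .variants import GENOTYPES, Genotype, SVRecord, SVType

logger = logging.getLogger(__name__)

PANEL_MAGIC = "#kmergt-panel"
PANEL_VERSION = 1
PANEL_COLUMNS = (
    "kmer_sequence", "sv_id", "role", "left_neighbor", "right_neighbor",
    "copies_00", "copies_01", "copies_11",
)


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file into a {name: sequence} dict (upper-cased)."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
    out = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return out


def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------- SV sets

def read_sv_file(path, fmt: Optional[str] = None) -> list[SVRecord]:
    """Parse SVs from BED or VCF (auto-detected from the extension)."""
    path = str(path)
    if fmt is None:
        base = path[:-3] if path.endswith(".gz") else path
        fmt = "VCF" if base.endswith(".vcf") else "BED"
    if fmt.upper() == "BED":
        return _read_sv_bed(path)
    if fmt.upper() == "VCF":
        return _read_sv_vcf(path)
    raise ValueError(f"unknown SV file format {fmt!r}")


def _read_sv_bed(path) -> list[SVRecord]:
    out = []
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected at least 4 BED columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                parts = fields[3].split(";")
                svtype = SVType(parts[0])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            sv_id = f"sv{len(out):05d}"
            seq = ""
            for extra in parts[1:]:
                if extra.startswith("seq="):
                    seq = extra[4:].upper()
                elif extra:
                    sv_id = extra
            out.append(SVRecord(sv_id, chrom, start, end, svtype, inserted_seq=seq))
    return out


def _read_sv_vcf(path) -> list[SVRecord]:
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for i, rec in enumerate(vcf):
            sv_id = rec.id or f"sv{i:05d}"
            alt = rec.alts[0] if rec.alts else None
            if alt is None:
                continue
            if alt.startswith("<"):
                svtype = SVType(rec.info.get("SVTYPE", alt.strip("<>")))
                start = rec.start + 1  # POS anchors the base before the event
                end = start if svtype is SVType.INS else rec.stop
                try:
                    seq = str(rec.info["SEQ"]).upper() if "SEQ" in rec.info else ""
                except (KeyError, ValueError):
                    seq = ""
                if svtype is SVType.INS and not seq:
                    logger.warning("%s: insertion without SEQ info", sv_id)
                out.append(SVRecord(sv_id, rec.chrom, start, end, svtype, seq))
            elif len(alt) > len(rec.ref):  # literal insertion
                out.append(
                    SVRecord(
                        sv_id, rec.chrom, rec.start + 1, rec.start + 1,
                        SVType.INS, inserted_seq=alt[len(rec.ref):].upper(),
                    )
                )
            else:  # literal deletion
                out.append(
                    SVRecord(
                        sv_id, rec.chrom, rec.start + 1,
                        rec.start + 1 + len(rec.ref) - len(alt), SVType.DEL,
                    )
                )
    return out


def write_sv_bed(svs: Sequence[SVRecord], path) -> None:
    with open(path, "w") as fh:
        for sv in svs:
            name = f"{sv.svtype.value};{sv.id}"
            if sv.inserted_seq:
                name += f";seq={sv.inserted_seq}"
            fh.write(f"{sv.chrom}\t{sv.start}\t{sv.end}\t{name}\n")


# ---------------------------------------------------------------- panel

def write_panel(panel: Panel, path, params: Optional[dict] = None) -> None:
    """Serialize a panel as versioned TSV (gzip if the path ends in .gz)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        header = [f"{PANEL_MAGIC}\tversion={PANEL_VERSION}\tk={panel.k}"]
        for key, val in (params or {}).items():
            header[0] += f"\t{key}={val}"
        fh.write(header[0] + "\n")
        for sv in panel.svs:
            seq = sv.inserted_seq or "."
            fh.write(
                f"#sv\t{sv.id}\t{sv.chrom}\t{sv.start}\t{sv.end}\t"
                f"{sv.svtype.value}\t{seq}\n"
            )
        fh.write("#columns\t" + "\t".join(PANEL_COLUMNS) + "\n")
        for p in list(panel.profiles) + list(panel.controls):
            left = decode_kmer(p.left_neighbor, p.k) if p.left_neighbor is not None else "."
            right = decode_kmer(p.right_neighbor, p.k) if p.right_neighbor is not None else "."
            fh.write(
                "\t".join(
                    [
                        decode_kmer(p.code, p.k), p.sv_id, p.role, left, right,
                        str(p.copies[0]), str(p.copies[1]), str(p.copies[2]),
                    ]
                )
                + "\n"
            )


def read_panel(path) -> Panel:
    opener = gzip.open if str(path).endswith(".gz") else open
    k = None
    svs: list[SVRecord] = []
    profiles: list[KmerProfile] = []
    controls: list[KmerProfile] = []
    with opener(path, "rt") as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith(PANEL_MAGIC):
            raise ValueError(f"{path}: not a k-mer panel file")
        for field in first.split("\t")[1:]:
            key, _, val = field.partition("=")
            if key == "k":
                k = int(val)
        if k is None:
            raise ValueError(f"{path}: panel header missing k")
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#sv\t"):
                _, sv_id, chrom, start, end, svtype, seq = line.split("\t")
                svs.append(
                    SVRecord(
                        sv_id, chrom, int(start), int(end), SVType(svtype),
                        inserted_seq="" if seq == "." else seq,
                    )
                )
                continue
            if line.startswith("#") or not line:
                continue
            seq, sv_id, role, left, right, c00, c01, c11 = line.split("\t")
            profile = KmerProfile(
                code=canonical(encode_kmer(seq), k),
                k=k,
                sv_id=sv_id,
                role=role,
                left_neighbor=canonical(encode_kmer(left), k) if left != "." else None,
                right_neighbor=canonical(encode_kmer(right), k) if right != "." else None,
                copies=(int(c00), int(c01), int(c11)),
            )
            (controls if sv_id == CONTROL_SV_ID else profiles).append(profile)
    return Panel(k=k, svs=svs, profiles=profiles, controls=controls)


# ---------------------------------------------------------------- reads

def iter_read_sequences(path) -> Iterator[str]:
    """Stream read sequences from FASTQ/FASTA (optionally gzip) or SAM/BAM.

    Alignment files are treated purely as read streams: secondary and
    supplementary records are skipped so each read is seen once.
    """
    path = str(path)
    base = path[:-3] if path.endswith(".gz") else path
    n_bad = 0
    if base.endswith((".sam", ".bam", ".cram")):
        with pysam.AlignmentFile(path, check_sq=False) as fh:
            for aln in fh.fetch(until_eof=True):
                if aln.is_secondary or aln.is_supplementary:
                    continue
                if aln.query_sequence:
                    yield aln.query_sequence
                else:
                    n_bad += 1
    else:
        with pysam.FastxFile(path) as fh:
            for rec in fh:
                if rec.sequence:
                    yield rec.sequence
                else:
                    n_bad += 1
    if n_bad:
        logger.warning("%s: skipped %d records without sequence", path, n_bad)


class ReadFiles:
    """Re-iterable read stream over one or more FASTQ/FASTA/SAM/BAM files."""

    def __init__(self, paths: Sequence):
        self.paths = [str(p) for p in paths]

    def chunks(self, batch: int = 20_000) -> Iterator[np.ndarray]:
        buf: list[str] = []
        for path in self.paths:
            for seq in iter_read_sequences(path):
                buf.append(seq)
                if len(buf) >= batch:
                    yield seqs_to_matrix(buf)
                    buf = []
        if buf:
            yield seqs_to_matrix(buf)


# ---------------------------------------------------------------- VCF out

def _vcf_header(svs: Sequence[SVRecord], sample: str, extra_meta: Optional[dict]):
    header = pysam.VariantHeader()
    for key, val in (extra_meta or {}).items():
        header.add_line(f"##kmergt_{key}={val}")
    for chrom in dict.fromkeys(sv.chrom for sv in svs):
        header.add_line(f"##contig=<ID={chrom}>")
    header.add_line(
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">'
    )
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">')
    header.add_line(
        '##INFO=<ID=NKMERS,Number=1,Type=Integer,Description="Supporting k-mers used">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=GL,Number=G,Type=Float,Description='
        '"Log10-scaled genotype likelihoods for 0/0, 0/1, 1/1">'
    )
    header.add_sample(sample)
    return header

_GT_TUPLE = {
    Genotype.HOM_REF: (0, 0),
    Genotype.HET: (0, 1),
    Genotype.HOM_ALT: (1, 1),
}


def write_genotype_vcf(
    calls: Sequence[GenotypeCall],
    svs: Sequence[SVRecord],
    path,
    sample: str = "SAMPLE",
    meta: Optional[dict] = None,
) -> None:
    """One VCF 4.2 record per SV with GT, log10 likelihoods and NKMERS.

    Missing calls (no supporting k-mers) are written as ``./.``.
    """
    by_id = {c.sv_id: c for c in calls}
    header = _vcf_header(svs, sample, meta)
    ln10 = float(np.log(10.0))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for sv in sorted(svs, key=lambda s: (s.chrom, s.start)):
            call = by_id.get(sv.id)
            rec = out.new_record(
                contig=sv.chrom,
                start=max(0, sv.start - 1),  # POS anchors the base before the event
                alleles=("N", f"<{sv.svtype.value}>"),
                id=sv.id,
            )
            rec.info["SVTYPE"] = sv.svtype.value
            rec.stop = max(sv.end, sv.start)
            if call is None or call.is_missing:
                rec.samples[sample]["GT"] = (None, None)
                rec.info["NKMERS"] = 0 if call is None else call.n_kmers
            else:
                rec.samples[sample]["GT"] = _GT_TUPLE[call.genotype]
                rec.samples[sample]["GL"] = [
                    call.loglik[g] / ln10 for g in GENOTYPES
                ]
                rec.info["NKMERS"] = call.n_kmers
            out.write(rec)


def write_truth_vcf(
    svs: Sequence[SVRecord], truth: dict[str, Genotype], path,
    sample: str = "TRUTH",
) -> None:
    """Write known genotypes in the same VCF layout as genotype output."""
    calls = [
        GenotypeCall(sv_id=sv.id, genotype=truth.get(sv.id), loglik=None, n_kmers=0)
        for sv in svs
    ]
    # truth VCFs carry no likelihoods; reuse the writer with GT only
    by_id = {c.sv_id: c for c in calls}
    header = _vcf_header(svs, sample, None)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for sv in sorted(svs, key=lambda s: (s.chrom, s.start)):
            call = by_id[sv.id]
            rec = out.new_record(
                contig=sv.chrom,
                start=max(0, sv.start - 1),
                alleles=("N", f"<{sv.svtype.value}>"),
                id=sv.id,
            )
            rec.info["SVTYPE"] = sv.svtype.value
            rec.stop = max(sv.end, sv.start)
            gt = truth.get(sv.id)
            rec.samples[sample]["GT"] = (None, None) if gt is None else _GT_TUPLE[gt]
            out.write(rec)


def read_genotype_vcf(path) -> dict[str, Optional[Genotype]]:
    """Genotypes keyed by record ID; ``None`` for missing (./.)."""
    out: dict[str, Optional[Genotype]] = {}
    with pysam.VariantFile(str(path)) as vcf:
        sample = list(vcf.header.samples)[0]
        for i, rec in enumerate(vcf):
            sv_id = rec.id or f"sv{i:05d}"
            gt = rec.samples[sample].get("GT")
            if gt is None or any(a is None for a in gt):
                out[sv_id] = None
            else:
                out[sv_id] = Genotype(int(sum(gt)))
    return out
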