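"""Data model, file readers/writers and window extraction.

All coordinates in memory are transcript-space, 1-based, inclusive.
BED-like annotation files on disk are 0-based half-open and converted on
read.  DNA input (T) is transcribed to U; mixed case is accepted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

_SNV_TOKEN = re.compile(r"^([ACGUT])(\d+)([ACGUT])$", re.IGNORECASE)


class ValidationError(ValueError):
    """Raised when an input record violates the data-model invariants."""


def normalize_rna(seq: str) -> str:
    """Uppercase a nucleotide string and transcribe T to U."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class TranscriptRecord:
    """An mRNA sequence with 1-based inclusive UTR spans and gene symbol."""

    transcript_id: str
    gene: str
    sequence: str
    utr5: tuple[int, int] | None = None
    utr3: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for name, span in (("utr5", self.utr5), ("utr3", self.utr3)):
            if span is None:
                continue
            s, e = span
            if not (1 <= s <= e <= n):
                raise ValidationError(
                    f"{self.transcript_id}: {name} span {span} outside [1, {n}]"
                )
        if self.utr5 is not None and self.utr3 is not None:
            if not self.utr5[1] < self.utr3[0]:
                raise ValidationError(
                    f"{self.transcript_id}: utr5 must end before utr3 starts"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Return the base at a 1-based position."""
        return self.sequence[position - 1]

    def in_utr5(self, position: int) -> bool:
        return self.utr5 is not None and self.utr5[0] <= position <= self.utr5[1]

    def in_utr3(self, position: int) -> bool:
        return self.utr3 is not None and self.utr3[0] <= position <= self.utr3[1]


@dataclass(frozen=True)
class SnvRecord:
    """A single-base substitution in 1-based transcript coordinates."""

    transcript_id: str
    position: int
    ref: str
    alt: str
    utr_label: str = "none"  # one of {"5", "3", "both", "none"}
    dbsnp_id: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError(
                f"{self.transcript_id}:{self.position} ref equals alt ({self.ref})"
            )
        if self.ref not in RNA_ALPHABET or self.alt not in RNA_ALPHABET:
            raise ValidationError(
                f"{self.transcript_id}:{self.position} non-ACGU allele "
                f"{self.ref}>{self.alt}"
            )
        if self.position < 1:
            raise ValidationError(f"position {self.position} must be >= 1")

    @property
    def token(self) -> str:
        """Compact notation, e.g. U1552G."""
        return f"{self.ref}{self.position}{self.alt}"


@dataclass(frozen=True)
class WindowPair:
    """Wild-type and mutant subsequences around one SNV.

    ``window_start`` is the 1-based transcript coordinate of the first
    window base; ``snv_offset`` is the 1-based position of the SNV inside
    the window.
    """

    wt_seq: str
    mt_seq: str
    window_start: int
    snv_offset: int

    def __post_init__(self) -> None:
        if len(self.wt_seq) != len(self.mt_seq):
            raise ValidationError("wt and mt windows differ in length")
        diffs = [
            k
            for k, (a, b) in enumerate(zip(self.wt_seq, self.mt_seq), start=1)
            if a != b
        ]
        if diffs != [self.snv_offset]:
            raise ValidationError(
                f"windows must differ exactly at snv_offset={self.snv_offset}, "
                f"found diffs at {diffs}"
            )

    def __len__(self) -> int:
        return len(self.wt_seq)

    def to_transcript(self, window_pos: int) -> int:
        """Map a 1-based window coordinate back to transcript space."""
        return self.window_start + window_pos - 1


@dataclass(frozen=True)
class ClipCluster:
    transcript_id: str
    start: int  # 1-based inclusive
    end: int
    bc: int

    def __post_init__(self) -> None:
        if self.bc < 0:
            raise ValidationError("biological complexity must be >= 0")


@dataclass(frozen=True)
class ConservedInterval:
    transcript_id: str
    start: int
    end: int
    source: str  # "cmfinder" or "rnaz"


@dataclass
class AnnotationBundle:
    """External annotations consumed by the two pipeline arms."""

    cancer_genes: set[str] = field(default_factory=set)
    conserved_intervals: dict[str, list[ConservedInterval]] = field(
        default_factory=dict
    )
    clip_clusters: dict[str, list[ClipCluster]] = field(default_factory=dict)
    expressed_mirnas: set[str] = field(default_factory=set)
    lung_cancer_mirnas: set[str] = field(default_factory=set)
    ld_pairs: list[tuple[SnvRecord, int, str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_transcripts(fasta_path, utr_table_path) -> list[TranscriptRecord]:
    """Read transcript FASTA plus a sidecar UTR span table.

    The table needs columns ``transcript_id``, ``gene``, ``utr5_start``,
    ``utr5_end``, ``utr3_start``, ``utr3_end`` (empty/0 span fields mean
    the UTR is absent).  FASTA entries without a UTR row are dropped with
    a warning.
    """
    table = pd.read_csv(utr_table_path, sep="\t", dtype={"transcript_id": str})
    rows = {str(r.transcript_id): r for r in table.itertuples(index=False)}
    records: list[TranscriptRecord] = []
    dropped = 0
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        tid = entry.id
        row = rows.get(tid)
        if row is None:
            dropped += 1
            logger.warning("transcript %s has no UTR row; dropped", tid)
            continue
        seq = normalize_rna(str(entry.seq))
        bad = set(seq) - RNA_ALPHABET
        if bad:
            logger.warning(
                "transcript %s contains non-ACGU characters %s", tid, sorted(bad)
            )
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene=str(row.gene),
                sequence=seq,
                utr5=_span(row, "utr5"),
                utr3=_span(row, "utr3"),
            )
        )
    if dropped:
        logger.warning("%d FASTA entries had no UTR annotation", dropped)
    return records


def _span(row, prefix: str) -> tuple[int, int] | None:
    s = getattr(row, f"{prefix}_start", None)
    e = getattr(row, f"{prefix}_end", None)
    if s is None or e is None or pd.isna(s) or pd.isna(e):
        return None
    s, e = int(s), int(e)
    if s == 0 and e == 0:
        return None
    if s > e:
        raise ValidationError(f"{row.transcript_id}: inverted {prefix} span ({s},{e})")
    return (s, e)


def write_transcripts(records: Sequence[TranscriptRecord], fasta_path, utr_table_path):
    with open(fasta_path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.transcript_id}\n{rec.sequence}\n")
    rows = []
    for rec in records:
        u5 = rec.utr5 or (0, 0)
        u3 = rec.utr3 or (0, 0)
        rows.append(
            dict(
                transcript_id=rec.transcript_id,
                gene=rec.gene,
                utr5_start=u5[0],
                utr5_end=u5[1],
                utr3_start=u3[0],
                utr3_end=u3[1],
            )
        )
    pd.DataFrame(rows).to_csv(utr_table_path, sep="\t", index=False)


def parse_snv_token(token: str) -> tuple[str, int, str]:
    """Parse compact notation like ``U1552G`` into (ref, position, alt)."""
    m = _SNV_TOKEN.match(token.strip())
    if m is None:
        raise ValidationError(f"unparsable SNV token {token!r}")
    ref, pos, alt = m.groups()
    return normalize_rna(ref), int(pos), normalize_rna(alt)


def read_snvs(tsv_path, transcripts: Sequence[TranscriptRecord]) -> list[SnvRecord]:
    """Read SNVs from TSV and validate against transcript sequences.

    Accepts either a ``snv`` token column (e.g. U1552G) or explicit
    ``position``/``ref``/``alt`` columns.  Records whose ref allele does
    not match the transcript base are excluded (counted in a warning);
    rows naming unknown transcripts are skipped likewise.
    """
    by_id = {t.transcript_id: t for t in transcripts}
    by_gene: dict[str, list[TranscriptRecord]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene, []).append(t)
    table = pd.read_csv(tsv_path, sep="\t", dtype=str)
    out: list[SnvRecord] = []
    unknown = mismatch = 0
    for row in table.itertuples(index=False):
        tid = str(row.transcript_id)
        tr = by_id.get(tid)
        if tr is None:
            unknown += 1
            continue
        if hasattr(row, "snv") and isinstance(row.snv, str):
            ref, pos, alt = parse_snv_token(row.snv)
        else:
            ref = normalize_rna(str(row.ref))
            alt = normalize_rna(str(row.alt))
            pos = int(row.position)
        if pos < 1 or pos > len(tr):
            raise ValidationError(f"{tid}: SNV position {pos} outside transcript")
        if tr.base(pos) != ref:
            mismatch += 1
            logger.warning(
                "%s:%d ref %s does not match transcript base %s; excluded",
                tid,
                pos,
                ref,
                tr.base(pos),
            )
            continue
        dbsnp = getattr(row, "dbsnp_id", None)
        if dbsnp is not None and (not isinstance(dbsnp, str) or not dbsnp):
            dbsnp = None
        snv = SnvRecord(tid, pos, ref, alt, dbsnp_id=dbsnp)
        mapped = _mapped_transcripts(snv, by_id, by_gene)
        out.append(
            SnvRecord(
                tid, pos, ref, alt, utr_label=classify_utr(snv, mapped), dbsnp_id=dbsnp
            )
        )
    if unknown:
        logger.warning("%d SNV rows named unknown transcripts; skipped", unknown)
    if mismatch:
        logger.warning("%d SNV rows failed the ref-allele check; excluded", mismatch)
    return out


def _mapped_transcripts(snv, by_id, by_gene) -> list[TranscriptRecord]:
    """Transcripts the SNV maps to: its own plus overlapping same-gene isoforms
    that carry the same base at the same transcript position."""
    tr = by_id[snv.transcript_id]
    mapped = [tr]
    for other in by_gene.get(tr.gene, []):
        if other.transcript_id == snv.transcript_id:
            continue
        if snv.position <= len(other) and other.base(snv.position) == snv.ref:
            mapped.append(other)
    return mapped


def write_snvs(snvs: Sequence[SnvRecord], tsv_path) -> None:
    rows = [
        dict(
            transcript_id=s.transcript_id,
            snv=s.token,
            position=s.position,
            ref=s.ref,
            alt=s.alt,
            utr_label=s.utr_label,
            dbsnp_id=s.dbsnp_id or "",
        )
        for s in snvs
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def classify_utr(snv: SnvRecord, transcript_set: Iterable[TranscriptRecord]) -> str:
    """Assign the UTR label of an SNV over every transcript it maps to.

    "5" if the position falls in the 5' UTR of all mapped transcripts,
    "3" for the 3' UTR, "both" when overlapping transcripts place it in a
    5' UTR on one and a 3' UTR on another, "none" otherwise.
    """
    in5 = in3 = False
    for tr in transcript_set:
        if tr.in_utr5(snv.position):
            in5 = True
        if tr.in_utr3(snv.position):
            in3 = True
    if in5 and in3:
        return "both"
    if in5:
        return "5"
    if in3:
        return "3"
    return "none"


def extract_window(
    snv: SnvRecord, transcript: TranscriptRecord, flank: int
) -> WindowPair:
    """Extract the +/- flank window around an SNV, clipped at transcript ends.

    Returns the wild-type window and the mutant window with the alternate
    base substituted at the SNV offset.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if transcript.base(snv.position) != snv.ref:
        raise ValidationError(
            f"{snv.transcript_id}:{snv.position} ref {snv.ref} does not match "
            f"transcript base {transcript.base(snv.position)}"
        )
    start = max(1, snv.position - flank)
    end = min(len(transcript), snv.position + flank)
    wt = transcript.sequence[start - 1 : end]
    offset = snv.position - start + 1
    mt = wt[: offset - 1] + snv.alt + wt[offset:]
    return WindowPair(wt_seq=wt, mt_seq=mt, window_start=start, snv_offset=offset)


def count_screen_space(n_mirnas: int, n_snvs: int) -> int:
    """Per-allele (miRNA, SNV) combination count of the screening space.

    The full screen runs each combination against both the wild-type and
    the mutant allele, i.e. twice this number of scans.
    """
    if n_mirnas < 0 or n_snvs < 0:
        raise ValueError("counts must be nonnegative")
    return n_mirnas * n_snvs


# ---------------------------------------------------------------------------
# annotation files (BED-like on disk: 0-based half-open)
# ---------------------------------------------------------------------------


def read_gene_list(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def read_conserved_bed(path) -> dict[str, list[ConservedInterval]]:
    """BED-like: transcript_id, start(0-based), end(half-open), source."""
    out: dict[str, list[ConservedInterval]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            tid, start, end, source = line.split()[:4]
            iv = ConservedInterval(tid, int(start) + 1, int(end), source)
            out.setdefault(tid, []).append(iv)
    return out


def write_conserved_bed(intervals: dict[str, list[ConservedInterval]], path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(intervals):
            for iv in intervals[tid]:
                fh.write(f"{tid}\t{iv.start - 1}\t{iv.end}\t{iv.source}\n")


def read_clip_bed(path) -> dict[str, list[ClipCluster]]:
    """BED-like with a BC column: transcript_id, start, end, name, bc."""
    out: dict[str, list[ClipCluster]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            tid, start, end = fields[0], int(fields[1]), int(fields[2])
            bc = int(fields[4]) if len(fields) > 4 else int(fields[3])
            out.setdefault(tid, []).append(ClipCluster(tid, start + 1, end, bc))
    return out


def write_clip_bed(clusters: dict[str, list[ClipCluster]], path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(clusters):
            for i, c in enumerate(clusters[tid]):
                fh.write(f"{tid}\t{c.start - 1}\t{c.end}\tcluster{i}\t{c.bc}\n")


def read_ld_pairs(
    path, snvs: Sequence[SnvRecord]
) -> list[tuple[SnvRecord, int, str, str]]:
    """TSV: transcript_id, snv (token), partner_position, partner_ref, partner_alt."""
    by_key = {(s.transcript_id, s.token): s for s in snvs}
    table = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for row in table.itertuples(index=False):
        key = (str(row.transcript_id), str(row.snv))
        snv = by_key.get(key)
        if snv is None:
            logger.warning("LD row names unknown SNV %s; skipped", key)
            continue
        out.append(
            (
                snv,
                int(row.partner_position),
                normalize_rna(str(row.partner_ref)),
                normalize_rna(str(row.partner_alt)),
            )
        )
    return out
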