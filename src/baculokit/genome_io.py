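"""Reading, writing and coordinate primitives for circular viral genomes.

Baculovirus genomes are circular dsDNA molecules of roughly 80-180 kb.  All
external coordinates in this package follow the GenBank convention: 1-based,
inclusive, with a feature that spans the replication origin represented as
``start > end`` on a circular record.  Internally, extraction linearizes the
circle by doubling the sequence, so origin-spanning coding sequences translate
exactly like any other.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation

__all__ = [
    "GenomeRecord",
    "FeatureRecord",
    "GenomeFormatError",
    "read_genome",
    "reverse_complement",
    "extract_region",
    "region_length",
    "translate_cds",
    "gc_content",
    "write_gff3",
    "read_gff3",
    "write_fasta",
]

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeFormatError(ValueError):
    """Raised for malformed input files or invalid sequences/coordinates."""


@dataclass
class FeatureRecord:
    """A single annotated feature in 1-based inclusive genome coordinates.

    ``start > end`` is only legal on a circular genome and denotes a feature
    running through the origin.
    """

    kind: str  # CDS, hr, repeat, misc
    start: int
    end: int
    strand: str  # '+' or '-'
    qualifiers: dict[str, str] = field(default_factory=dict)

    def validate(self, genome: "GenomeRecord") -> None:
        n = genome.length
        if not (1 <= self.start <= n and 1 <= self.end <= n):
            raise GenomeFormatError(
                f"feature {self.kind} {self.start}..{self.end} outside genome of {n} bp"
            )
        if self.start > self.end and not genome.circular:
            raise GenomeFormatError(
                f"origin-spanning feature {self.start}..{self.end} on a linear genome"
            )
        if self.strand not in "+-":
            raise GenomeFormatError(f"invalid strand {self.strand!r}")


@dataclass
class GenomeRecord:
    """A genome sequence with its annotated features."""

    id: str
    sequence: str
    circular: bool = True
    features: list[FeatureRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeFormatError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _VALID
        if bad:
            raise GenomeFormatError(
                f"record {self.id!r} contains characters outside A/C/G/T/N: "
                f"{sorted(bad)!r} (lowercase and IUPAC ambiguity codes are rejected)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def reverse_complement(seq: str) -> str:
    """Reverse complement over the strict alphabet {A,C,G,T,N}."""
    bad = set(seq) - _VALID
    if bad:
        raise GenomeFormatError(f"non-nucleotide characters in sequence: {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def region_length(start: int, end: int, genome_length: int) -> int:
    """Length in bp of the 1-based inclusive extent start..end, wrapping if start > end."""
    if start <= end:
        return end - start + 1
    return genome_length - start + 1 + end


def extract_region(genome: GenomeRecord, start: int, end: int, strand: str = "+") -> str:
    """Extract the extent start..end (1-based inclusive) on the given strand.

    On circular genomes ``start > end`` wraps through the origin.
    """
    n = genome.length
    if not (1 <= start <= n and 1 <= end <= n):
        raise GenomeFormatError(f"coordinates {start}..{end} outside genome of {n} bp")
    if start <= end:
        sub = genome.sequence[start - 1 : end]
    else:
        if not genome.circular:
            raise GenomeFormatError("origin-spanning extent on a linear genome")
        sub = genome.sequence[start - 1 :] + genome.sequence[:end]
    return reverse_complement(sub) if strand == "-" else sub


_STOPS = {"TAA", "TAG", "TGA"}


def translate_cds(
    genome: GenomeRecord,
    start: int,
    end: int,
    strand: str = "+",
    strict: bool = True,
) -> str:
    """Translate a CDS extent with the standard genetic code.

    The extent is expected to include the terminal stop codon (GenBank
    convention); the stop is dropped from the returned protein.  An internal
    stop raises in strict mode; in lenient mode the protein is returned with
    ``*`` at the offending positions.
    """
    nt = extract_region(genome, start, end, strand)
    if len(nt) % 3 != 0:
        raise GenomeFormatError(
            f"CDS extent {start}..{end} ({strand}) has length {len(nt)}, not a multiple of 3"
        )
    prot = str(Seq(nt).translate(table=1))
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        if strict:
            pos = prot.index("*")
            raise GenomeFormatError(
                f"internal stop codon at codon {pos + 1} of CDS {start}..{end} ({strand})"
            )
    return prot


def gc_content(seq: str) -> float:
    """G+C percentage over unambiguous bases, rounded half-up to 2 decimals.

    N is excluded from the denominator; a sequence of only N is an error.
    """
    bad = set(seq) - _VALID
    if bad:
        raise GenomeFormatError(f"non-nucleotide characters in sequence: {sorted(bad)!r}")
    denom = sum(seq.count(b) for b in "ACGT")
    if denom == 0:
        raise GenomeFormatError("cannot compute GC content: no unambiguous bases")
    gc = seq.count("G") + seq.count("C")
    frac = Decimal(100 * gc) / Decimal(denom)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# File input


def read_genome(path: str | Path, format: str = "genbank") -> GenomeRecord:
    """Read a genome from a GenBank flat file or FASTA.

    GenBank CDS features are preserved as :class:`FeatureRecord` entries with
    their coordinates, strand and text qualifiers.  An origin-spanning GenBank
    join is collapsed to a single ``start > end`` feature.  Circularity is
    taken from the GenBank topology; FASTA records default to circular, the
    convention for baculovirus genome deposits.
    """
    path = Path(path)
    if format not in ("genbank", "fasta"):
        raise ValueError(f"unknown format {format!r}")
    try:
        records = list(SeqIO.parse(str(path), format))
    except Exception as exc:  # biopython raises assorted types on bad input
        raise GenomeFormatError(f"failed to parse {path} as {format}: {exc}") from exc
    if not records:
        raise GenomeFormatError(f"no records found in {path}")
    rec = records[0]
    seq = str(rec.seq).upper().replace("U", "T")
    circular = True
    features: list[FeatureRecord] = []
    if format == "genbank":
        topology = rec.annotations.get("topology", "circular")
        circular = topology == "circular"
        for feat in rec.features:
            if feat.type not in ("CDS", "repeat_region", "misc_feature"):
                continue
            kind = {"CDS": "CDS", "repeat_region": "hr", "misc_feature": "misc"}[feat.type]
            strand = "-" if feat.location.strand == -1 else "+"
            if isinstance(feat.location, CompoundLocation):
                parts = sorted(feat.location.parts, key=lambda p: int(p.start))
                # an origin join looks like (x..L) + (1..y)
                start = int(parts[-1].start) + 1
                end = int(parts[0].end)
                if not (start > end):
                    start = int(parts[0].start) + 1
                    end = int(parts[-1].end)
            else:
                start = int(feat.location.start) + 1
                end = int(feat.location.end)
            quals = {k: v[0] if isinstance(v, list) else str(v) for k, v in feat.qualifiers.items()}
            features.append(FeatureRecord(kind=kind, start=start, end=end, strand=strand, qualifiers=quals))
    genome = GenomeRecord(id=rec.id, sequence=seq, circular=circular, features=features)
    for f in features:
        f.validate(genome)
    return genome


def write_fasta(genome: GenomeRecord, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3

_STRAND_ORDER = {"+": 0, "-": 1}


def _feature_sort_key(f: FeatureRecord) -> tuple:
    return (f.start, _STRAND_ORDER.get(f.strand, 2), f.end)


def write_gff3(genome: GenomeRecord, features: Iterable[FeatureRecord], path: str | Path) -> None:
    """Write features as GFF3 (1-based inclusive coordinates).

    An origin-spanning feature is emitted as two part lines sharing one ``ID``
    attribute so that standard GFF3 consumers see valid intervals;
    :func:`read_gff3` reconstitutes the single circular feature.
    """
    feats = sorted(features, key=_feature_sort_key)
    n = genome.length
    kind_to_so = {"CDS": "CDS", "hr": "repeat_region", "repeat": "repeat_region", "misc": "misc_feature"}
    buf = io.StringIO()
    buf.write("##gff-version 3\n")
    buf.write(f"##sequence-region {genome.id} 1 {n}\n")
    for i, f in enumerate(feats):
        f.validate(genome)
        fid = f.qualifiers.get("ID", f"{f.kind.lower()}{i + 1}")
        attrs = [f"ID={fid}", f"baculokit_kind={f.kind}"]
        for k, v in f.qualifiers.items():
            if k != "ID":
                attrs.append(f"{k}={v}")
        so_type = kind_to_so.get(f.kind, "misc_feature")
        if f.start <= f.end:
            buf.write(
                f"{genome.id}\tbaculokit\t{so_type}\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{';'.join(attrs)}\n"
            )
        else:
            part_attrs = ";".join(attrs + ["is_circular=true"])
            buf.write(f"{genome.id}\tbaculokit\t{so_type}\t{f.start}\t{n}\t.\t{f.strand}\t.\t{part_attrs}\n")
            buf.write(f"{genome.id}\tbaculokit\t{so_type}\t1\t{f.end}\t.\t{f.strand}\t.\t{part_attrs}\n")
    Path(path).write_text(buf.getvalue())


def read_gff3(path: str | Path) -> list[FeatureRecord]:
    """Read features written by :func:`write_gff3`, merging origin-spanning parts."""
    so_to_kind = {"CDS": "CDS", "repeat_region": "hr", "misc_feature": "misc"}
    by_id: dict[str, list[tuple[int, int, str, str, dict]] ] = {}
    order: list[str] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise GenomeFormatError(f"malformed GFF3 line: {line!r}")
        _, _, so_type, start, end, _, strand, _, attr_text = cols
        attrs = dict(kv.split("=", 1) for kv in attr_text.split(";") if "=" in kv)
        fid = attrs.get("ID", f"_anon{len(order)}")
        kind = attrs.pop("baculokit_kind", so_to_kind.get(so_type, "misc"))
        if fid not in by_id:
            order.append(fid)
            by_id[fid] = []
        by_id[fid].append((int(start), int(end), strand, kind, attrs))
    out: list[FeatureRecord] = []
    for fid in order:
        parts = by_id[fid]
        quals = {k: v for k, v in parts[0][4].items() if k != "is_circular"}
        quals["ID"] = fid
        if len(parts) == 1:
            s, e, strand, kind, _ = parts[0]
        else:
            parts_sorted = sorted(parts)
            # origin join: the low part starts at 1, the high part ends at L
            s = parts_sorted[-1][0]
            e = parts_sorted[0][1]
            strand, kind = parts[0][2], parts[0][3]
        out.append(FeatureRecord(kind=kind, start=s, end=e, strand=strand, qualifiers=quals))
    return out
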