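"""Genome records, sequence I/O and coding-sequence translation.

The central container is :class:`GenomeRecord`: one nucleotide sequence
(circular by default, as is typical for deposited phage genomes assembled
from circularly permuted virion DNA) plus its annotated CDS and tRNA
features.  Coordinates are 1-based inclusive everywhere, matching GenBank;
a feature may wrap the circular junction, in which case ``start > end``
and ``wraps`` is set.

Reading and writing of FASTA and GenBank goes through Bio.SeqIO; GFF3
(with an optional ``##FASTA`` section) goes through gffutils.  Sequences
are normalised on input: upper-cased, RNA ``U`` mapped to ``T``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, CompoundLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

IUPAC_NT = set("ACGTN")

#: reverse-complement table over the alphabet we accept
_RC = str.maketrans("ACGTN", "TGCAN")


class GenomeIOError(ValueError):
    """Raised for malformed sequence or annotation input."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class Feature:
    """A CDS or tRNA gene on a genome, 1-based inclusive coordinates."""

    locus_tag: str
    kind: Literal["CDS", "tRNA"]
    start: int
    end: int
    strand: Literal["+", "-"]
    product: str = ""
    category: str | None = None  # functional category A..L, if assigned
    anticodon: str | None = None  # tRNA only, DNA alphabet, 5'->3'
    amino_acid: str | None = None  # tRNA only; 3-letter code, or Sup/Pyl
    wraps: bool = False  # spans the circular junction (start > end)
    malformed: bool = False  # CDS whose length is not divisible by 3

    def __post_init__(self) -> None:
        if self.kind == "tRNA" and not self.anticodon:
            raise GenomeIOError(f"tRNA feature {self.locus_tag} lacks an anticodon")
        if self.kind != "tRNA" and self.anticodon:
            raise GenomeIOError(f"non-tRNA feature {self.locus_tag} carries an anticodon")
        if not self.wraps and self.start > self.end:
            raise GenomeIOError(
                f"feature {self.locus_tag}: start {self.start} > end {self.end} "
                "but not flagged as wrapping the circular junction"
            )

    def length(self, genome_length: int | None = None) -> int:
        """Feature length in nt; wrapped features need the genome length."""
        if not self.wraps:
            return self.end - self.start + 1
        if genome_length is None:
            raise GenomeIOError("wrapped feature length requires genome_length")
        return genome_length - self.start + 1 + self.end


@dataclass
class GenomeRecord:
    id: str
    sequence: str
    topology: Literal["circular", "linear"] = "circular"
    features: list[Feature] = field(default_factory=list)
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise GenomeIOError(f"record {self.id}: empty sequence")
        bad = next((i for i, c in enumerate(self.sequence) if c not in IUPAC_NT), None)
        if bad is not None:
            raise GenomeIOError(
                f"record {self.id}: non-IUPAC character {self.sequence[bad]!r} "
                f"at position {bad + 1}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def circular(self) -> bool:
        return self.topology == "circular"

    def cds(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "CDS"]

    def trnas(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "tRNA"]

    def gc_percent(self) -> float:
        s = self.sequence
        gc = s.count("G") + s.count("C")
        denom = len(s) - s.count("N")
        return 100.0 * gc / denom if denom else 0.0


def normalise_sequence(raw: str, record_id: str = "?") -> str:
    seq = raw.upper().replace("U", "T")
    bad = next((i for i, c in enumerate(seq) if c not in IUPAC_NT), None)
    if bad is not None:
        raise GenomeIOError(
            f"record {record_id}: non-IUPAC character {seq[bad]!r} at position {bad + 1}"
        )
    return seq


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, topology: str = "circular") -> list[GenomeRecord]:
    """Read a (multi-)FASTA file into GenomeRecords.

    Sequences are upper-cased and U is mapped to T.  An empty file is an
    error; so is any character outside {A,C,G,T,N,U} (reported with its
    1-based position).
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            GenomeRecord(
                id=rec.id,
                sequence=normalise_sequence(str(rec.seq), rec.id),
                topology=topology,  # type: ignore[arg-type]
                description=rec.description,
            )
        )
    if not records:
        raise GenomeIOError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description) for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


# ---------------------------------------------------------------------------
# GenBank / GFF3 annotations

def _strand_symbol(biopython_strand: int | None) -> str:
    return "-" if biopython_strand == -1 else "+"


def _feature_from_seqfeature(sf, locus_fallback: str, genome_length: int) -> Feature:
    q = sf.qualifiers
    locus = q.get("locus_tag", [locus_fallback])[0]
    strand = _strand_symbol(sf.location.strand)
    parts = sorted(sf.location.parts, key=lambda p: int(p.start))
    start = int(parts[0].start) + 1
    end = int(parts[-1].end)
    wraps = False
    if len(parts) > 1 and int(parts[0].start) == 0 and int(parts[-1].end) == genome_length:
        # join(x..L, 1..y): a feature across the circular junction
        wraps = True
        start = int(parts[-1].start) + 1
        end = int(parts[0].end)
    kind = "CDS" if sf.type == "CDS" else "tRNA"
    anticodon = None
    amino_acid = None
    if kind == "tRNA":
        amino_acid, anticodon = _parse_trna_qualifiers(q)
    feat = Feature(
        locus_tag=locus,
        kind=kind,  # type: ignore[arg-type]
        start=start,
        end=end,
        strand=strand,  # type: ignore[arg-type]
        product=q.get("product", [""])[0],
        anticodon=anticodon,
        amino_acid=amino_acid,
        wraps=wraps,
    )
    if kind == "CDS" and feat.length(genome_length) % 3 != 0:
        feat.malformed = True
    return feat


def _parse_trna_qualifiers(q) -> tuple[str | None, str | None]:
    """Pull amino acid and anticodon out of tRNA qualifiers.

    Accepts ``/product="tRNA-Pro"`` plus ``/anticodon`` in either the
    structured GenBank form ``(pos:...,aa:Pro,seq:tgg)`` or a bare 3-mer,
    or a ``/note="Pro (TGG)"`` style free-text fallback.
    """
    import re

    amino = None
    anticodon = None
    product = q.get("product", [""])[0]
    m = re.search(r"tRNA-([A-Za-z]{3})", product)
    if m:
        amino = m.group(1)
    for raw in q.get("anticodon", []):
        m = re.search(r"seq\s*:\s*([acgtuACGTU]{3})", raw)
        if m:
            anticodon = m.group(1)
        elif re.fullmatch(r"[acgtuACGTU]{3}", raw.strip()):
            anticodon = raw.strip()
        m = re.search(r"aa\s*:\s*([A-Za-z]{3})", raw)
        if m:
            amino = m.group(1)
    if anticodon is None:
        for raw in q.get("note", []):
            m = re.search(r"\(([acgtuACGTU]{3})\)", raw)
            if m:
                anticodon = m.group(1)
                break
    if anticodon is not None:
        anticodon = normalise_sequence(anticodon)
    return amino, anticodon


def read_annotations(path: str | Path, fmt: str = "genbank") -> GenomeRecord:
    """Read an annotated genome from GenBank or GFF3(+FASTA).

    Only CDS and tRNA features are kept; other feature kinds are counted
    and logged.  A CDS whose length is not divisible by 3 is kept and
    flagged ``malformed``; a feature extending beyond the sequence is an
    error.
    """
    if fmt == "genbank":
        return _read_genbank(path)
    if fmt == "gff3":
        return _read_gff3(path)
    raise GenomeIOError(f"unknown annotation format {fmt!r}")


def _read_genbank(path: str | Path) -> GenomeRecord:
    try:
        rec = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise GenomeIOError(f"{path}: no GenBank records found") from None
    topology = rec.annotations.get("topology", "circular")
    genome = GenomeRecord(
        id=rec.id or rec.name,
        sequence=normalise_sequence(str(rec.seq), rec.id),
        topology="circular" if topology == "circular" else "linear",
        description=rec.description,
    )
    skipped = 0
    n_auto = 0
    for sf in rec.features:
        if sf.type not in ("CDS", "tRNA"):
            skipped += 1
            continue
        n_auto += 1
        feat = _feature_from_seqfeature(sf, f"{sf.type}{n_auto:03d}", len(genome))
        _check_bounds(feat, len(genome), genome.circular)
        genome.features.append(feat)
    if skipped:
        log.info("%s: ignored %d non-CDS/tRNA features", path, skipped)
    return genome


def _read_gff3(path: str | Path) -> GenomeRecord:
    import gffutils

    text = Path(path).read_text()
    fasta_part = None
    if "##FASTA" in text:
        gff_part, fasta_part = text.split("##FASTA", 1)
    else:
        gff_part = text
    db = gffutils.create_db(
        gff_part, ":memory:", from_string=True, merge_strategy="create_unique",
        keep_order=True,
    )
    if fasta_part is None:
        raise GenomeIOError(f"{path}: GFF3 without a ##FASTA section")
    from io import StringIO

    recs = list(SeqIO.parse(StringIO(fasta_part.lstrip("\n")), "fasta"))
    if not recs:
        raise GenomeIOError(f"{path}: empty ##FASTA section")
    rec = recs[0]
    genome = GenomeRecord(
        id=rec.id, sequence=normalise_sequence(str(rec.seq), rec.id)
    )
    skipped = 0
    for f in db.all_features():
        if f.featuretype not in ("CDS", "tRNA"):
            skipped += 1
            continue
        anticodon = None
        amino = None
        if f.featuretype == "tRNA":
            anticodon = (f.attributes.get("anticodon", [None]) or [None])[0]
            if anticodon:
                anticodon = normalise_sequence(anticodon)
            amino = (f.attributes.get("amino_acid", [None]) or [None])[0]
        feat = Feature(
            locus_tag=(f.attributes.get("locus_tag", [f.id or "feature"]) or ["feature"])[0],
            kind=f.featuretype,  # type: ignore[arg-type]
            start=f.start,
            end=f.end,
            strand="-" if f.strand == "-" else "+",
            product=(f.attributes.get("product", [""]) or [""])[0],
            anticodon=anticodon,
            amino_acid=amino,
        )
        if feat.kind == "CDS" and feat.length(len(genome)) % 3 != 0:
            feat.malformed = True
        _check_bounds(feat, len(genome), genome.circular)
        genome.features.append(feat)
    genome.features.sort(key=lambda f: f.start)
    if skipped:
        log.info("%s: ignored %d non-CDS/tRNA features", path, skipped)
    return genome


def _check_bounds(feat: Feature, genome_length: int, circular: bool) -> None:
    if feat.start < 1 or feat.end > genome_length or feat.start > genome_length:
        raise GenomeIOError(
            f"feature {feat.locus_tag}: coordinates {feat.start}..{feat.end} "
            f"outside sequence of length {genome_length}"
        )
    if feat.wraps and not circular:
        raise GenomeIOError(
            f"feature {feat.locus_tag} wraps the junction of a linear genome"
        )


def write_genbank(record: GenomeRecord, path: str | Path) -> None:
    """Write a GenomeRecord as a GenBank flat file (round-trippable)."""
    rec = SeqRecord(Seq(record.sequence), id=record.id, name=record.id.split(".")[0][:16],
                    description=record.description)
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = record.topology
    for f in record.features:
        strand = -1 if f.strand == "-" else 1
        if f.wraps:
            loc = CompoundLocation(
                [
                    FeatureLocation(f.start - 1, len(record), strand),
                    FeatureLocation(0, f.end, strand),
                ]
                if strand == 1
                else [
                    FeatureLocation(0, f.end, strand),
                    FeatureLocation(f.start - 1, len(record), strand),
                ]
            )
        else:
            loc = FeatureLocation(f.start - 1, f.end, strand)
        quals = {"locus_tag": [f.locus_tag]}
        if f.product:
            quals["product"] = [f.product]
        if f.kind == "tRNA" and f.anticodon:
            quals["anticodon"] = [f.anticodon]
            if f.amino_acid:
                quals["product"] = [f"tRNA-{f.amino_acid}"]
        rec.features.append(SeqFeature(loc, type=f.kind, qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


# ---------------------------------------------------------------------------
# Feature extraction and translation

def feature_sequence(record: GenomeRecord, feature: Feature) -> str:
    """Extract a feature's nucleotide sequence, strand-aware.

    Minus-strand features are reverse-complemented; features wrapping the
    circular junction are concatenated across it.  Wrapping on a linear
    genome is an error.
    """
    _check_bounds(feature, len(record), record.circular)
    s = record.sequence
    if feature.wraps:
        nt = s[feature.start - 1 :] + s[: feature.end]
    else:
        nt = s[feature.start - 1 : feature.end]
    if feature.strand == "-":
        nt = reverse_complement(nt)
    return nt


START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class Translation:
    protein: str
    internal_stop: bool = False
    start_recoded: bool = False  # GTG/TTG rendered as Met


def translate_cds(cds_nt: str, table: int = 11) -> Translation:
    """Translate an in-frame CDS under the bacterial code (table 11).

    Alternative starts GTG/TTG are rendered as Met at position 1 (fMet
    initiation); the trailing stop codon is stripped; an internal stop is
    flagged on the result rather than silently dropped.  Codons containing
    N translate to X.
    """
    cds_nt = cds_nt.upper().replace("U", "T")
    if len(cds_nt) % 3 != 0:
        raise GenomeIOError(f"CDS length {len(cds_nt)} not divisible by 3")
    if len(cds_nt) < 6:
        raise GenomeIOError("CDS shorter than two codons")
    aa = str(Seq(cds_nt).translate(table=table))
    start_recoded = False
    if cds_nt[:3] in ("GTG", "TTG") and aa and aa[0] != "M":
        aa = "M" + aa[1:]
        start_recoded = True
    if aa.endswith("*"):
        aa = aa[:-1]
    internal_stop = "*" in aa
    return Translation(protein=aa, internal_stop=internal_stop,
                       start_recoded=start_recoded)


def cds_protein(record: GenomeRecord, feature: Feature, table: int = 11) -> Translation:
    """Convenience: extract and translate one CDS feature."""
    return translate_cds(feature_sequence(record, feature), table=table)
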