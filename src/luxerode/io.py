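"""Readers/writers for the external formats the pipeline touches.

Formats: FASTA + GFF3 (annotated genomes), FASTA / relaxed-PHYLIP multiple
alignments, an 8-column pileup TSV (contig, pos, ref, depth, A, C, G, T),
and newick trees. write/read round-trips are identity on valid inputs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import AnnotatedGenome, Feature, FEATURE_KINDS

log = logging.getLogger(__name__)

PILEUP_COLUMNS = ["contig", "pos", "ref", "depth", "A", "C", "G", "T"]


# ---------------------------------------------------------------------------
# alignments


@dataclass
class MultipleAlignment:
    """Equal-length aligned sequences with '-' gaps."""

    sequence_ids: list
    sequences: list
    alphabet: str = "nucleotide"  # or "amino-acid"

    def __post_init__(self):
        if len(self.sequence_ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in count")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            bad = [i for i, s in zip(self.sequence_ids, self.sequences)
                   if len(s) != len(self.sequences[0])]
            raise ValueError(f"ragged alignment rows: {bad}")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def __getitem__(self, seq_id: str) -> str:
        return self.sequences[self.sequence_ids.index(seq_id)]


def _guess_alphabet(seqs) -> str:
    residues = set("".join(seqs).upper()) - set("-.")
    return "nucleotide" if residues <= set("ACGTUNRYKMBVDHW S") else "amino-acid"


def read_alignment(path, dialect: str = "fasta") -> MultipleAlignment:
    """Read a FASTA or relaxed-PHYLIP multiple alignment.

    Rows of unequal length are rejected with the offending ids named.
    """
    fmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}.get(dialect)
    if fmt is None:
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    if fmt == "fasta":
        # AlignIO rejects ragged fasta opaquely; read records for a better error
        records = list(SeqIO.parse(str(path), "fasta"))
        ids = [r.id for r in records]
        seqs = [str(r.seq).upper() for r in records]
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            ref = len(seqs[0])
            bad = [i for i, s in zip(ids, seqs) if len(s) != ref]
            raise ValueError(f"alignment rows of unequal length: {bad}")
    else:
        aln = AlignIO.read(str(path), fmt)
        ids = [r.id for r in aln]
        seqs = [str(r.seq).upper() for r in aln]
    return MultipleAlignment(ids, seqs, _guess_alphabet(seqs))


def write_alignment(aln: MultipleAlignment, path, dialect: str = "fasta") -> None:
    from Bio.Align import MultipleSeqAlignment
    records = [SeqRecord(Seq(s), id=i, description="")
               for i, s in zip(aln.sequence_ids, aln.sequences)]
    fmt = {"fasta": "fasta", "phylip": "phylip-relaxed"}[dialect]
    if fmt == "fasta":
        SeqIO.write(records, str(path), fmt)
    else:
        AlignIO.write(MultipleSeqAlignment(records), str(path), fmt)


# ---------------------------------------------------------------------------
# pileup


@dataclass
class PileupTable:
    """Per-site depth and ACGT counts; depth == A+C+G+T on every row."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=PILEUP_COLUMNS))

    def __post_init__(self):
        t = self.table
        if list(t.columns) != PILEUP_COLUMNS:
            raise ValueError(f"pileup columns must be {PILEUP_COLUMNS}")
        if len(t):
            sums = t[["A", "C", "G", "T"]].sum(axis=1)
            bad = t.index[sums != t["depth"]]
            if len(bad):
                raise ValueError(
                    f"pileup depth != A+C+G+T at row(s) {list(bad[:5])}")

    def __len__(self):
        return len(self.table)


def read_pileup(path) -> PileupTable:
    """Read the 8-column pileup TSV; empty files give an empty table."""
    try:
        t = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return PileupTable()
    missing = [c for c in PILEUP_COLUMNS if c not in t.columns]
    if missing:
        raise ValueError(f"pileup missing column(s) {missing}")
    t = t[PILEUP_COLUMNS]
    sums = t[["A", "C", "G", "T"]].sum(axis=1)
    bad = t.index[sums != t["depth"]]
    if len(bad):
        # +2: header line plus 1-based file line numbering
        raise ValueError(
            f"pileup depth != sum of base counts at line {bad[0] + 2}")
    return PileupTable(t)


def write_pileup(pileup: PileupTable, path) -> None:
    pileup.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trees


def read_tree(path_or_string) -> dendropy.Tree:
    """Read a newick tree (rooted or unrooted) with branch lengths."""
    s = str(path_or_string)
    if not s.lstrip().startswith("(") and len(s) < 4096 and Path(s).exists():
        s = Path(s).read_text()
    if s.count("(") != s.count(")"):
        # dendropy's message omits position; report the offset ourselves
        depth = 0
        for off, ch in enumerate(s):
            depth += ch == "("
            depth -= ch == ")"
            if depth < 0:
                break
        else:
            off = len(s)
        raise ValueError(f"unmatched parenthesis in newick near offset {off}")
    try:
        tree = dendropy.Tree.get(data=s, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"newick parse error: {exc}") from exc
    return tree


def write_tree(tree: dendropy.Tree, path=None) -> str:
    """Write newick preserving branch lengths to 10 significant digits."""
    out = tree.as_string(schema="newick", suppress_rooting=True,
                         unquoted_underscores=True,
                         real_value_format_specifier=".10g").strip()
    if path is not None:
        Path(path).write_text(out + "\n")
    return out


# ---------------------------------------------------------------------------
# genomes (FASTA + GFF3)


def _parse_gff3_attributes(text: str) -> dict:
    attrs = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
        else:
            attrs[part.strip()] = "true"
    return attrs


def read_genome(fasta_path, gff3_path, genome_id: str | None = None) -> AnnotatedGenome:
    """Assemble an AnnotatedGenome from a contig FASTA and a GFF3.

    Every CDS/rRNA/tRNA line becomes a Feature; a ``pseudo`` or
    ``status=pseudogene`` attribute sets status=pseudogene. Unknown feature
    kinds are skipped with a logged count; a coordinate outside its contig is
    a hard error naming the feature.
    """
    contigs = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    features = []
    skipped = 0
    n_anon = 0
    for lineno, line in enumerate(Path(gff3_path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"{gff3_path}: line {lineno}: expected 9 columns")
        contig, _source, kind, start, end, _score, strand, _phase, attr_text = cols
        if kind not in FEATURE_KINDS:
            skipped += 1
            continue
        attrs = _parse_gff3_attributes(attr_text)
        fid = attrs.get("ID")
        if fid is None:
            n_anon += 1
            fid = f"feature_{n_anon:06d}"
        status = "functional"
        if attrs.get("pseudo", "").lower() in ("true", "1", "yes") or \
                attrs.get("status") == "pseudogene":
            status = "pseudogene"
        elif attrs.get("status") in ("unknown",):
            status = "unknown"
        tags = frozenset(t for t in attrs.get("category", "").split(",") if t)
        features.append(Feature(
            feature_id=fid, contig_id=contig, start=int(start), end=int(end),
            strand=strand if strand in "+-" else "+", kind=kind, status=status,
            product=attrs.get("product", ""), category_tags=tags))
    if skipped:
        log.info("read_genome: skipped %d non-CDS/rRNA/tRNA features", skipped)
    gid = genome_id or Path(fasta_path).stem
    return AnnotatedGenome(gid, contigs, features, source=str(gff3_path)).validate()


def write_genome(genome: AnnotatedGenome, fasta_path, gff3_path) -> None:
    """Write contigs as FASTA and features as GFF3 (round-trips read_genome)."""
    records = [SeqRecord(Seq(s), id=cid, description="")
               for cid, s in genome.contigs.items()]
    SeqIO.write(records, str(fasta_path), "fasta")
    lines = ["##gff-version 3"]
    for cid, s in genome.contigs.items():
        lines.append(f"##sequence-region {cid} 1 {len(s)}")
    for f in sorted(genome.features, key=lambda f: (f.contig_id, f.start, f.feature_id)):
        attrs = [f"ID={f.feature_id}"]
        if f.product:
            attrs.append(f"product={f.product}")
        if f.status == "pseudogene":
            attrs.append("pseudo=true")
        elif f.status == "unknown":
            attrs.append("status=unknown")
        if f.category_tags:
            attrs.append("category=" + ",".join(sorted(f.category_tags)))
        lines.append("\t".join([
            f.contig_id, "luxerode", f.kind, str(f.start), str(f.end), ".",
            f.strand, "0" if f.kind == "CDS" else ".", ";".join(attrs)]))
    Path(gff3_path).write_text("\n".join(lines) + "\n")


def read_fasta_proteome(path) -> dict:
    """Protein FASTA as an id -> sequence dict."""
    return {r.id: str(r.seq).upper().rstrip("*")
            for r in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict, path) -> None:
    with open(path, "w") as fh:
        for sid, s in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(s), 70):
                fh.write(s[i:i + 70] + "\n")
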