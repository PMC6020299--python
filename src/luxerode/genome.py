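"""Shared genome data model: contigs plus typed, status-flagged features.

Coordinates are 1-based inclusive on the forward strand at every public
interface. Sequences of minus-strand features are reverse-complemented on
extraction; coordinates always refer to the forward strand.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn",
                            "TGCAYRMKVBHDNtgcayrmkvbhdn")

FEATURE_KINDS = ("CDS", "rRNA", "tRNA")
STATUSES = ("functional", "pseudogene", "unknown")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Feature:
    """A genomic feature (CDS, rRNA or tRNA) with functional status.

    start/end are 1-based inclusive forward-strand coordinates, start <= end.
    """

    feature_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "CDS"
    status: str = "functional"
    product: str = ""
    category_tags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"feature {self.feature_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id}: bad strand {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"feature {self.feature_id}: unknown kind {self.kind!r}")
        if self.status not in STATUSES:
            raise ValueError(f"feature {self.feature_id}: bad status {self.status!r}")
        if not isinstance(self.category_tags, frozenset):
            self.category_tags = frozenset(self.category_tags)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def with_status(self, status: str) -> "Feature":
        return replace(self, status=status)


@dataclass
class AnnotatedGenome:
    """Contig sequences plus typed features.

    Invariants (checked in ``validate``): contig ids unique (guaranteed by the
    dict), feature ids unique, feature coordinates inside their contig.
    """

    genome_id: str
    contigs: dict  # contig_id -> sequence (str)
    features: list  # of Feature
    source: str = ""

    def validate(self) -> "AnnotatedGenome":
        seen = set()
        for f in self.features:
            if f.feature_id in seen:
                raise ValueError(f"duplicate feature_id {f.feature_id}")
            seen.add(f.feature_id)
            if f.contig_id not in self.contigs:
                raise ValueError(
                    f"feature {f.feature_id}: unknown contig {f.contig_id}")
            clen = len(self.contigs[f.contig_id])
            if f.start < 1 or f.end > clen:
                raise ValueError(
                    f"feature {f.feature_id}: coordinates {f.start}..{f.end} "
                    f"outside contig {f.contig_id} (length {clen})")
            if (f.kind == "CDS" and f.status == "functional"
                    and f.length % 3 != 0):
                log.warning("functional CDS %s length %d not divisible by 3",
                            f.feature_id, f.length)
        return self

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def feature_seq(self, feature: Feature) -> str:
        """Feature sequence, reverse-complemented for minus-strand features."""
        s = self.contigs[feature.contig_id][feature.start - 1:feature.end]
        return revcomp(s) if feature.strand == "-" else s

    def cds_features(self, status: str | None = None) -> list:
        out = [f for f in self.features if f.kind == "CDS"]
        if status is not None:
            out = [f for f in out if f.status == status]
        return out

    def gc_fraction(self) -> float:
        gc = at = 0
        for s in self.contigs.values():
            up = s.upper()
            gc += up.count("G") + up.count("C")
            at += up.count("A") + up.count("T")
        return gc / (gc + at) if gc + at else 0.0

    def summary(self) -> dict:
        """Genome-overview counts: size, CDS/pseudogene/RNA tallies."""
        cds = self.cds_features()
        return {
            "genome_id": self.genome_id,
            "genome_size_bp": self.total_length,
            "n_contigs": len(self.contigs),
            "gc_percent": round(100 * self.gc_fraction(), 1),
            "total_cds": len(cds),
            "complete_cds": sum(1 for f in cds if f.status == "functional"),
            "pseudogenes": sum(1 for f in cds if f.status == "pseudogene"),
            "rrna": sum(1 for f in self.features if f.kind == "rRNA"),
            "trna": sum(1 for f in self.features if f.kind == "tRNA"),
        }
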