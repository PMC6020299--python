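"""Pseudogene classification against a reference proteome.

A locus is called a possible pseudogene when its best reference hit shows a
query/subject full-length ratio below 0.60 or an amino-acid similarity
(BLOSUM62 positives over aligned columns) below 0.30; strict inequalities.
Loci with no acceptable hit are "orphan" — the rule needs a hit to compare
against. "Length" is amino-acid length of the full translated query over the
full subject protein length, not the aligned span.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

from Bio.Seq import Seq

from .align import ProteinAlignment, align_proteins
from .genome import AnnotatedGenome

log = logging.getLogger(__name__)

THETA_LEN = 0.60
THETA_SIM = 0.30
MIN_SCORE_FLOOR = 50.0

_PREFILTER_K = 4
_PREFILTER_TOP = 25


@dataclass
class ProteinHit:
    """Best-scoring reference hit for a query protein."""

    alignment: ProteinAlignment
    query_length: int
    subject_length: int

    def __post_init__(self):
        if self.query_length <= 0 or self.subject_length <= 0:
            raise ValueError("zero-length protein in ProteinHit")

    @property
    def length_ratio(self) -> float:
        return self.query_length / self.subject_length

    @property
    def similarity_frac(self) -> float:
        return self.alignment.similarity_frac


def translate_cds(genome: AnnotatedGenome, feature, readthrough: bool = False) -> str:
    """Translate a CDS feature.

    By default translation stops at the first internal stop codon (logged;
    the prefix is kept, not dropped), matching how truncation-degraded loci
    are handled downstream. With ``readthrough=True`` internal stops become
    X instead — the conceptual full-length translation used when censusing
    decayed transposase fragments.
    """
    nt = genome.feature_seq(feature)
    nt = nt[:len(nt) - len(nt) % 3]
    aa = str(Seq(nt).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        if readthrough:
            return aa.replace("*", "X")
        log.debug("CDS %s: internal stop; translating to first stop",
                  feature.feature_id)
        aa = aa.split("*", 1)[0]
    return aa


def _kmers(seq: str, k: int = _PREFILTER_K) -> set:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


class ReferenceIndex:
    """A reference proteome with an inverted k-mer index for candidate seeding.

    Build once, query many times: ``candidates`` returns the subjects sharing
    the most k-mers with a query (BLAST-like seeding), so full dynamic
    programming runs only on a short candidate list.
    """

    def __init__(self, proteome: dict, k: int = _PREFILTER_K):
        if not proteome:
            raise ValueError("empty reference proteome")
        self.proteome = proteome
        self.k = k
        self._postings: dict = {}
        for sid, seq in proteome.items():
            for km in _kmers(seq, k):
                self._postings.setdefault(km, []).append(sid)

    def candidates(self, query_seq: str, top: int) -> list:
        hits = Counter()
        for km in _kmers(query_seq, self.k):
            for sid in self._postings.get(km, ()):
                hits[sid] += 1
        if not hits:
            return sorted(self.proteome)[:top]
        ranked = sorted(hits.items(), key=lambda kv: (-kv[1], kv[0]))
        return [sid for sid, _ in ranked[:top]]


def best_hit(query_seq: str, reference_proteome,
             min_score_floor: float = MIN_SCORE_FLOOR,
             prefilter_top: int | None = None, **align_kw) -> ProteinHit | None:
    """Highest-scoring reference protein for a query, or None below the floor.

    Ties on score go to the lexicographically smaller subject id.
    ``reference_proteome`` may be a plain dict or a prebuilt ReferenceIndex;
    for large references the k-mer prefilter limits full dynamic programming
    to the ``prefilter_top`` most k-mer-similar subjects, while references of
    up to 2*prefilter_top subjects are searched exhaustively.
    """
    index = (reference_proteome if isinstance(reference_proteome, ReferenceIndex)
             else None)
    proteome = index.proteome if index else reference_proteome
    if not proteome:
        raise ValueError("empty reference proteome")
    top = _PREFILTER_TOP if prefilter_top is None else prefilter_top
    if len(proteome) > 2 * top:
        if index is None:
            index = ReferenceIndex(proteome)
        subjects = index.candidates(query_seq, top)
    else:
        subjects = sorted(proteome)
    best: ProteinHit | None = None
    for sid in subjects:
        sseq = proteome[sid]
        if not sseq:
            continue
        aln = align_proteins(query_seq, sseq, subject_id=sid, **align_kw)
        if aln.score < min_score_floor:
            continue
        if best is None or aln.score > best.alignment.score or (
                aln.score == best.alignment.score
                and sid < best.alignment.subject_id):
            best = ProteinHit(aln, len(query_seq), len(sseq))
    return best


def classify_locus(hit: ProteinHit | None,
                   theta_len: float = THETA_LEN,
                   theta_sim: float = THETA_SIM) -> str:
    """functional / pseudogene / orphan per the length-or-similarity rule."""
    if hit is None:
        return "orphan"
    if hit.length_ratio < theta_len or hit.similarity_frac < theta_sim:
        return "pseudogene"
    return "functional"


def call_pseudogenes(genome: AnnotatedGenome, reference_proteome: dict,
                     theta_len: float = THETA_LEN, theta_sim: float = THETA_SIM,
                     min_score_floor: float = MIN_SCORE_FLOOR,
                     **align_kw):
    """Classify every CDS in a genome against a reference proteome.

    Returns (genome_with_statuses, summary, per_locus) where per_locus maps
    feature_id -> dict(best_subject, length_ratio, similarity_frac, status).
    Idempotent: reclassifying the returned genome gives identical calls.
    """
    if not isinstance(reference_proteome, ReferenceIndex) and \
            len(reference_proteome) > 2 * _PREFILTER_TOP:
        reference_proteome = ReferenceIndex(reference_proteome)
    per_locus = {}
    new_features = []
    for f in genome.features:
        if f.kind != "CDS":
            new_features.append(f)
            continue
        aa = translate_cds(genome, f)
        if not aa:
            status, rec = "pseudogene", {
                "best_subject": None, "length_ratio": 0.0,
                "similarity_frac": 0.0}
        else:
            hit = best_hit(aa, reference_proteome,
                           min_score_floor=min_score_floor, **align_kw)
            status = classify_locus(hit, theta_len, theta_sim)
            rec = {
                "best_subject": None if hit is None else hit.alignment.subject_id,
                "length_ratio": None if hit is None else round(hit.length_ratio, 4),
                "similarity_frac": None if hit is None else round(hit.similarity_frac, 4),
            }
        rec["status"] = status
        per_locus[f.feature_id] = rec
        new_features.append(f.with_status(
            "pseudogene" if status == "pseudogene" else
            "functional" if status == "functional" else "unknown"))
    counts = Counter(r["status"] for r in per_locus.values())
    summary = {
        "n_total_cds": len(per_locus),
        "n_functional": counts.get("functional", 0),
        "n_pseudogene": counts.get("pseudogene", 0),
        "n_orphan": counts.get("orphan", 0),
    }
    out = AnnotatedGenome(genome.genome_id, genome.contigs, new_features,
                          genome.source)
    return out, summary, per_locus
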