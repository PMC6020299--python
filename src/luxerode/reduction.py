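"""Genome-reduction summary statistics.

Ortholog-based average nucleotide identity (ANI) over reciprocal-best-hit
CDS pairs, percent-reduction metrics against free-living relatives,
functional-category gene counts, and amino-acid pathway completeness.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .genome import AnnotatedGenome
from .pseudogenes import best_hit, translate_cds

log = logging.getLogger(__name__)


@dataclass
class OrthologPair:
    """A reciprocal-best-hit CDS pair with codon-level nucleotide identity."""

    gene_id_a: str
    gene_id_b: str
    nucleotide_identity: float  # percent over aligned CDS columns
    aligned_length_nt: int

    def __post_init__(self):
        if not 0.0 <= self.nucleotide_identity <= 100.0:
            raise ValueError("identity out of [0,100]")


def _best_map(queries: dict, reference: dict, **kw) -> dict:
    out = {}
    for qid in sorted(queries):
        hit = best_hit(queries[qid], reference, **kw)
        if hit is not None:
            out[qid] = hit
    return out


def ortholog_pairs(genome_a: AnnotatedGenome, genome_b: AnnotatedGenome,
                   min_score_floor: float = 50.0) -> list:
    """Reciprocal best hits between functional CDS sets of two genomes.

    Nucleotide identity is computed by back-mapping the protein alignment to
    codons: for every aligned residue pair, the two codons are compared
    base-by-base; identity = matching nt / (3 x aligned columns) x 100.
    """
    prot_a, nt_a = {}, {}
    for f in genome_a.cds_features("functional"):
        aa = translate_cds(genome_a, f)
        if aa:
            prot_a[f.feature_id] = aa
            nt_a[f.feature_id] = genome_a.feature_seq(f)
    prot_b, nt_b = {}, {}
    for f in genome_b.cds_features("functional"):
        aa = translate_cds(genome_b, f)
        if aa:
            prot_b[f.feature_id] = aa
            nt_b[f.feature_id] = genome_b.feature_seq(f)
    if not prot_a or not prot_b:
        return []
    ab = _best_map(prot_a, prot_b, min_score_floor=min_score_floor)
    ba = _best_map(prot_b, prot_a, min_score_floor=min_score_floor)
    pairs = []
    from .align import align_proteins
    for qa, hit in sorted(ab.items()):
        qb = hit.alignment.subject_id
        back = ba.get(qb)
        if back is None or back.alignment.subject_id != qa:
            continue
        # re-align in canonical (lexicographic) order so ANI(A,B) == ANI(B,A)
        # exactly even where the optimal path is tie-ambiguous
        if qa <= qb:
            aln = align_proteins(prot_a[qa], prot_b[qb])
            swap = False
        else:
            aln = align_proteins(prot_b[qb], prot_a[qa])
            swap = True
        # walk the alignment, comparing codons at aligned residue columns
        seq_q = nt_b[qb] if swap else nt_a[qa]
        seq_s = nt_a[qa] if swap else nt_b[qb]
        ia, ib = aln.q_start - 1, aln.s_start - 1  # residue indices
        match = total = 0
        for ca, cb in zip(aln.query_aln, aln.subject_aln):
            if ca != "-" and cb != "-":
                cod_a = seq_q[3 * ia:3 * ia + 3]
                cod_b = seq_s[3 * ib:3 * ib + 3]
                for x, y in zip(cod_a, cod_b):
                    total += 1
                    match += x == y
            ia += ca != "-"
            ib += cb != "-"
        if total == 0:
            continue
        pairs.append(OrthologPair(qa, qb, 100.0 * match / total, total))
    return pairs


def ani(pairs: list, length_weighted: bool = True) -> float:
    """Average nucleotide identity (percent) over ortholog pairs.

    Length-weighted by default: sum(identity_i * len_i) / sum(len_i).
    """
    if not pairs:
        raise ValueError("ani needs at least one ortholog pair")
    if length_weighted:
        wsum = sum(p.aligned_length_nt for p in pairs)
        return sum(p.nucleotide_identity * p.aligned_length_nt
                   for p in pairs) / wsum
    return sum(p.nucleotide_identity for p in pairs) / len(pairs)


def reduction_stats(target_count: float, reference_mean_count: float) -> float:
    """Percent reduction of a target count vs a reference mean.

    Negative when the target exceeds the reference (reported as such).
    """
    if reference_mean_count <= 0:
        raise ValueError("reference_mean_count must be > 0")
    return 100.0 * (1.0 - target_count / reference_mean_count)


def category_counts(genome: AnnotatedGenome, category_map: dict | None = None,
                    include_pseudogenes: bool = False) -> dict:
    """Gene counts per functional category (functional CDS by default).

    Categories come from each feature's own tags plus an optional
    gene-label -> categories map; a gene in several categories contributes
    to each. Unmapped, untagged genes tally under "uncategorized".
    """
    counts: dict = {}
    statuses = ("functional", "pseudogene") if include_pseudogenes \
        else ("functional",)
    for f in genome.cds_features():
        if f.status not in statuses:
            continue
        cats = set(f.category_tags)
        if category_map:
            extra = category_map.get(f.feature_id) or category_map.get(f.product)
            if extra:
                cats |= set(extra if not isinstance(extra, str) else [extra])
        if not cats:
            cats = {"uncategorized"}
        for c in cats:
            counts[c] = counts.get(c, 0) + 1
    return dict(sorted(counts.items()))


def read_category_map(tsv_path) -> dict:
    """gene label -> list of categories, from a 2-column TSV (label, category)."""
    t = pd.read_csv(tsv_path, sep="\t", header=None,
                    names=["label", "category"])
    out: dict = {}
    for _, row in t.iterrows():
        out.setdefault(row["label"], []).append(row["category"])
    return out


@dataclass
class PathwayDef:
    """An amino-acid synthesis pathway: ordered enzyme (gene label) list."""

    pathway_id: str
    enzymes: list

    def __post_init__(self):
        if not self.enzymes:
            raise ValueError(f"pathway {self.pathway_id}: empty enzyme list")


def read_pathways(tsv_path) -> list:
    """Pathway definitions from a TSV: pathway_id <tab> comma-separated enzymes."""
    t = pd.read_csv(tsv_path, sep="\t")
    return [PathwayDef(row["pathway_id"],
                       [e.strip() for e in str(row["enzymes"]).split(",")])
            for _, row in t.iterrows()]


def pathway_completeness(genome: AnnotatedGenome, pathway_defs: list) -> dict:
    """Per-pathway enzyme presence among functional genes.

    An enzyme is present when some functional CDS carries its label as the
    product; a pathway is complete iff every enzyme is present. Enzymes
    present only as pseudogenes do not count.
    """
    functional = {f.product for f in genome.cds_features("functional")}
    functional |= {f.feature_id for f in genome.cds_features("functional")}
    per = {}
    n_complete = 0
    for pw in pathway_defs:
        present = sum(1 for e in pw.enzymes if e in functional)
        complete = present == len(pw.enzymes)
        n_complete += complete
        per[pw.pathway_id] = {"n_present": present,
                              "n_required": len(pw.enzymes),
                              "complete": complete}
    return {"pathways": per, "n_complete": n_complete,
            "n_total": len(pathway_defs)}
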