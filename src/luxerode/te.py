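"""Transposable-element census and burst detection.

Classifies proteome entries into insertion-sequence (IS) families by
best-scoring alignment to family representatives, calls per-copy
completeness (>= 90% of the reference length AND both terminal inverted
repeats present), measures the TE share of coding sequences, finds
insertion-free regions, and tests within-family transposase phylogenies for
the star-on-a-long-stem geometry of a single expansion burst.

Trees are built by neighbor joining on Poisson-corrected protein distances:
the burst statistic needs branch-length geometry, not model-based support,
and NJ keeps the census self-contained.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit

from .align import align_proteins
from .genome import AnnotatedGenome, revcomp

log = logging.getLogger(__name__)

DISTANCE_CAP = 10.0
RATIO_SINGLE = 3.0  # stem/crown ratio calling a single expansion


@dataclass
class ISReference:
    """One IS family: representative transposase + expected IR geometry."""

    family_id: str
    representative_id: str
    representative_seq: str
    full_length_aa: int
    ir_min_len: int = 10
    ir_window: int = 100

    def __post_init__(self):
        if self.full_length_aa <= 0:
            raise ValueError("full_length_aa must be > 0")


@dataclass
class TERecord:
    """One transposase copy: family call, decay state, coordinates."""

    feature_id: str
    family_id: str
    identity_to_ref: float
    aligned_fraction_of_ref: float
    has_terminal_irs: bool = False
    contig_id: str = ""
    start: int = 0
    end: int = 0

    @property
    def completeness(self) -> str:
        return ("complete" if self.aligned_fraction_of_ref >= 0.9
                and self.has_terminal_irs else "fragment")


def load_is_reference(fasta_path, tsv_path) -> list:
    """IS reference set from a representative-protein FASTA + metadata TSV.

    TSV columns: family_id, representative_id, full_length_aa, ir_min_len,
    ir_window.
    """
    import pandas as pd
    from .io import read_fasta_proteome
    seqs = read_fasta_proteome(fasta_path)
    meta = pd.read_csv(tsv_path, sep="\t")
    refs = []
    for _, row in meta.iterrows():
        rid = row["representative_id"]
        if rid not in seqs:
            raise ValueError(f"representative {rid} missing from FASTA")
        refs.append(ISReference(
            family_id=row["family_id"], representative_id=rid,
            representative_seq=seqs[rid],
            full_length_aa=int(row["full_length_aa"]),
            ir_min_len=int(row.get("ir_min_len", 10)),
            ir_window=int(row.get("ir_window", 100))))
    return refs


def classify_transposases(proteome: dict, is_reference: list,
                          min_identity: float = 0.3,
                          min_coverage: float = 0.3) -> list:
    """Assign each protein to at most one IS family by best alignment score.

    A protein is assigned when its best family alignment reaches both
    ``min_identity`` (over aligned columns) and ``min_coverage`` (aligned
    subject span over the family's full protein length); otherwise it stays
    unassigned (absent from the result).
    """
    if not is_reference:
        raise ValueError("empty IS reference set")
    records = []
    for pid in sorted(proteome):
        seq = proteome[pid]
        if not seq:
            continue
        best = None
        for ref in sorted(is_reference, key=lambda r: r.family_id):
            aln = align_proteins(seq, ref.representative_seq,
                                 query_id=pid, subject_id=ref.family_id)
            if best is None or aln.score > best[0].score:
                best = (aln, ref)
        aln, ref = best
        identity = aln.identity_frac
        coverage = (aln.s_end - aln.s_start + 1) / ref.full_length_aa \
            if aln.n_aligned_columns else 0.0
        if identity >= min_identity and coverage >= min_coverage:
            records.append(TERecord(
                feature_id=pid, family_id=ref.family_id,
                identity_to_ref=round(identity, 4),
                aligned_fraction_of_ref=round(coverage, 4)))
    return records


@njit(cache=True)
def _best_ir_pair(up, down_rc, min_len, max_mismatch):
    """Longest (upstream, downstream reverse complement) match pair.

    ``down_rc`` is the reverse complement of the downstream window so an
    inverted repeat becomes a direct match. Returns (len, i, j, mismatches)
    with i, j 0-based offsets in the two windows, or (0,-1,-1,0).
    """
    best_len, best_i, best_j, best_mm = 0, -1, -1, 0
    n, m = len(up), len(down_rc)
    max_l = min(n, m)
    for L in range(max_l, min_len - 1, -1):
        for i in range(n - L + 1):
            for j in range(m - L + 1):
                mm = 0
                ok = True
                for k in range(L):
                    if up[i + k] != down_rc[j + k]:
                        mm += 1
                        if mm > max_mismatch:
                            ok = False
                            break
                if ok:
                    if (L > best_len or (L == best_len and
                                         (mm < best_mm or
                                          (mm == best_mm and
                                           (i < best_i or
                                            (i == best_i and j < best_j)))))):
                        best_len, best_i, best_j, best_mm = L, i, j, mm
        if best_len:
            break
    return best_len, best_i, best_j, best_mm


_NT_CODE = {c: i for i, c in enumerate("ACGTN")}


def _encode_nt(s):
    return np.array([_NT_CODE.get(c, 4) for c in s.upper()], dtype=np.int8)


def find_terminal_irs(contig_seq: str, feature_coords, window: int = 100,
                      min_len: int = 10, max_mismatch: int = 2):
    """Longest terminal inverted repeat flanking an element, or None.

    Searches a +-``window`` bp region around each element boundary (clamped
    at contig ends) for the longest sequence pair u / reverse-complement(u)
    with at most ``max_mismatch`` mismatches and length >= ``min_len``.
    Returns ((u_start, u_end), (v_start, v_end), n_mismatches) in 1-based
    contig coordinates.
    """
    start, end = feature_coords
    L = len(contig_seq)
    u_lo = max(0, start - 1 - window)
    u_hi = min(L, start - 1 + window)
    d_lo = max(0, end - window)
    d_hi = min(L, end + window)
    if u_lo >= u_hi or d_lo >= d_hi:
        log.debug("find_terminal_irs: window clamped to nothing at contig edge")
        return None
    up = contig_seq[u_lo:u_hi]
    down = contig_seq[d_lo:d_hi]
    blen, i, j, mm = _best_ir_pair(_encode_nt(up), _encode_nt(revcomp(down)),
                                   min_len, max_mismatch)
    if blen < min_len or blen == 0:
        return None
    u_start = u_lo + i + 1
    # j indexes into revcomp(down): map back to forward coordinates
    v_end = d_hi - j
    v_start = v_end - blen + 1
    return (u_start, u_start + blen - 1), (v_start, v_end), int(mm)


def te_fraction(n_te_genes: int, n_total_cds: int) -> float:
    """TE share of coding sequences, in percent."""
    if n_total_cds <= 0:
        raise ValueError("n_total_cds must be > 0")
    if n_te_genes > n_total_cds:
        raise ValueError("n_te_genes > n_total_cds")
    return 100.0 * n_te_genes / n_total_cds


def insertion_free_regions(genome: AnnotatedGenome, te_records: list,
                           min_span: int = 20000) -> list:
    """Maximal TE-free intervals >= min_span, with the functional genes inside.

    Intervals run between consecutive TE features (and contig ends).
    Returns dicts: contig, start, end (1-based inclusive), genes (feature ids
    of functional features fully inside).
    """
    te_ids = {r.feature_id for r in te_records}
    spans = {}
    for f in genome.features:
        if f.feature_id in te_ids:
            spans.setdefault(f.contig_id, []).append((f.start, f.end))
    out = []
    for contig_id, seq in genome.contigs.items():
        L = len(seq)
        tes = sorted(spans.get(contig_id, []))
        bounds = [0] + [e for _, e in tes]
        uppers = [s - 1 for s, _ in tes] + [L]
        for lo, hi in zip(bounds, uppers):
            start, end = lo + 1, hi
            if end - start + 1 >= min_span:
                genes = [f.feature_id for f in genome.features
                         if f.contig_id == contig_id and f.status == "functional"
                         and f.start >= start and f.end <= end]
                out.append({"contig": contig_id, "start": start, "end": end,
                            "genes": genes})
    return out


# ---------------------------------------------------------------------------
# distances, neighbor joining, burst geometry


def distance_matrix(sequences: dict, model: str = "poisson"):
    """Pairwise protein distances (p-distance or Poisson-corrected -ln(1-p)).

    Pairs are aligned globally; p is the mismatch fraction over aligned
    columns. Saturated pairs (p >= 1) are capped at 10. Returns (ids, matrix).
    """
    if len(sequences) < 2:
        raise ValueError("need >= 2 sequences")
    if model not in ("p-distance", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    ids = sorted(sequences)
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = align_proteins(sequences[ids[i]], sequences[ids[j]],
                                 mode="global")
            p = (1.0 - aln.n_identical / aln.n_aligned_columns
                 if aln.n_aligned_columns else 1.0)
            if model == "p-distance":
                d = p
            elif p >= 1.0 - 1e-12:
                log.warning("saturated distance between %s and %s capped",
                            ids[i], ids[j])
                d = DISTANCE_CAP
            else:
                d = min(-np.log(1.0 - p), DISTANCE_CAP)
            D[i, j] = D[j, i] = d
    return ids, D


class NJTree:
    """Unrooted tree from neighbor joining, stored as an edge list."""

    def __init__(self, labels):
        self.labels = list(labels)  # leaf name or None for internal nodes
        self.edges = []  # (node_a, node_b, length)

    def add_node(self, label=None) -> int:
        self.labels.append(label)
        return len(self.labels) - 1

    def adjacency(self):
        adj = {i: [] for i in range(len(self.labels))}
        for a, b, w in self.edges:
            adj[a].append((b, w))
            adj[b].append((a, w))
        return adj

    def leaf_indices(self) -> dict:
        return {lab: i for i, lab in enumerate(self.labels) if lab is not None}

    def path_length(self, a_label: str, b_label: str) -> float:
        idx = self.leaf_indices()
        adj = self.adjacency()
        start, goal = idx[a_label], idx[b_label]
        stack = [(start, -1, 0.0)]
        while stack:
            node, prev, dist = stack.pop()
            if node == goal:
                return dist
            for nxt, w in adj[node]:
                if nxt != prev:
                    stack.append((nxt, node, dist + w))
        raise RuntimeError("disconnected tree")

    def to_newick(self) -> str:
        adj = self.adjacency()
        # root at the last internal node for serialization only
        root = max(i for i, lab in enumerate(self.labels) if lab is None) \
            if any(lab is None for lab in self.labels) else 0

        def rec(node, prev):
            kids = [(n, w) for n, w in adj[node] if n != prev]
            if not kids:
                return self.labels[node]
            inner = ",".join(f"{rec(n, node)}:{w:.10g}" for n, w in kids)
            return f"({inner})"

        return rec(root, -1) + ";"


def neighbor_joining(labels, D) -> NJTree:
    """Standard neighbor joining; exact on additive matrices.

    Negative branch lengths are clamped to 0 with the deficit moved to the
    sister branch.
    """
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    tree = NJTree(list(labels))
    M = D.copy()
    ids = list(range(n))  # tree-node id of each row of M
    while len(ids) > 2:
        m = M.shape[0]
        r = M.sum(axis=1)
        Q = (m - 2) * M - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        ii, jj = np.unravel_index(np.argmin(Q), Q.shape)
        if ii > jj:
            ii, jj = jj, ii
        a, b = ids[ii], ids[jj]
        u = tree.add_node()
        la = 0.5 * M[ii, jj] + (r[ii] - r[jj]) / (2 * (m - 2))
        lb = M[ii, jj] - la
        if la < 0:
            lb += -la
            la = 0.0
        if lb < 0:
            la += -lb
            lb = 0.0
        tree.edges.append((a, u, float(la)))
        tree.edges.append((b, u, float(lb)))
        du = 0.5 * (M[ii] + M[jj] - M[ii, jj])
        keep = [k for k in range(m) if k not in (ii, jj)]
        M2 = np.empty((m - 1, m - 1))
        M2[:-1, :-1] = M[np.ix_(keep, keep)]
        M2[-1, :-1] = M2[:-1, -1] = du[keep]
        M2[-1, -1] = 0.0
        M = M2
        ids = [ids[k] for k in keep] + [u]
    a, b = ids
    tree.edges.append((a, b, float(max(M[0, 1], 0.0))))
    return tree


@dataclass
class BurstReport:
    """Expansion geometry of one TE family's copies within a genome."""

    family_id: str
    n_copies: int
    monophyletic: bool
    stem_length: float
    mean_crown_depth: float
    burst_ratio: float
    verdict: str  # single_expansion | multiple_expansions | no_expansion
    note: str = ""


def _copy_clades(tree: NJTree, copies: set):
    """Maximal copy-only clades when the tree is rooted at an outgroup leaf.

    Returns a list of (stem_length, [copy labels], crown_root_node).
    """
    idx = tree.leaf_indices()
    adj = tree.adjacency()
    out_leaf = next(i for lab, i in idx.items() if lab not in copies)

    clades = []

    def leaves_below(node, prev):
        kids = [(n, w) for n, w in adj[node] if n != prev]
        if not kids:
            return [tree.labels[node]]
        out = []
        for n, _ in kids:
            out.extend(leaves_below(n, node))
        return out

    def visit(node, prev, edge_len):
        labs = leaves_below(node, prev)
        if labs and all(l in copies for l in labs):
            clades.append((edge_len, labs, node, prev))
            return
        for n, w in adj[node]:
            if n != prev:
                visit(n, node, w)

    visit(out_leaf, -1, 0.0)
    return clades


def _crown_depths(tree: NJTree, node, prev):
    adj = tree.adjacency()

    def rec(n, p, dist):
        kids = [(k, w) for k, w in adj[n] if k != p]
        if not kids:
            return [dist]
        out = []
        for k, w in kids:
            out.extend(rec(k, n, dist + w))
        return out

    return rec(node, prev, 0.0)


def burst_test(copies: dict, outgroup: dict,
               ratio_single: float = RATIO_SINGLE,
               distance_model: str = "poisson") -> BurstReport:
    """Classify a family's within-genome copies as one burst, several, or none.

    Builds an NJ tree over copies + outgroup transposases. A clade of copies
    separated from the outgroup by a stem at least ``ratio_single`` times its
    mean crown (root-to-tip) depth reads as a rapid radiation on a long stem.
    """
    family = "unknown"
    if len(copies) < 2:
        return BurstReport(family, len(copies), False, 0.0, 0.0, 0.0,
                           "no_expansion", note="fewer than 2 copies")
    if not outgroup:
        raise ValueError("need at least one outgroup sequence")
    seqs = {f"copy::{k}": v for k, v in copies.items()}
    seqs.update({f"out::{k}": v for k, v in outgroup.items()})
    ids, D = distance_matrix(seqs, model=distance_model)
    tree = neighbor_joining(ids, D)
    copy_set = {i for i in ids if i.startswith("copy::")}
    clades = _copy_clades(tree, copy_set)
    # clades holds maximal copy-only subtrees; geometry per clade
    scored = []
    for stem, labs, node, prev in clades:
        if len(labs) == 1:
            scored.append((stem, labs, 0.0, np.inf if stem > 0 else 0.0))
            continue
        depths = _crown_depths(tree, node, prev)
        crown = float(np.mean(depths))
        ratio = stem / crown if crown > 0 else np.inf
        scored.append((stem, labs, crown, ratio))
    mono = len(clades) == 1
    if mono:
        stem, labs, crown, ratio = scored[0]
        verdict = ("single_expansion"
                   if ratio >= ratio_single else "no_expansion")
        return BurstReport(family, len(copies), True, float(stem), crown,
                           float(min(ratio, 1e9)), verdict)
    big = [s for s in scored if len(s[1]) >= 2 and s[3] >= ratio_single]
    if len(big) >= 2:
        verdict = "multiple_expansions"
    else:
        verdict = "no_expansion"
    stem = max(s[0] for s in scored)
    crowns = [s[2] for s in scored if len(s[1]) >= 2]
    crown = float(np.mean(crowns)) if crowns else 0.0
    ratio = stem / crown if crown > 0 else 0.0
    return BurstReport(family, len(copies), False, float(stem), crown,
                       float(ratio), verdict)


# ---------------------------------------------------------------------------
# genome-level census


def census(genome: AnnotatedGenome, is_reference: list,
           min_identity: float = 0.3, min_coverage: float = 0.3,
           ir_window: int = 100, ir_min_len: int = 10,
           ir_max_mismatch: int = 2) -> dict:
    """Full TE census of a genome: per-copy records + family count table.

    Returns {"records": [TERecord...], "family_counts": {family: n},
    "n_total_cds": int, "te_percent_of_cds": float, "n_complete": int}.
    """
    from .pseudogenes import translate_cds
    proteome = {}
    by_id = {}
    for f in genome.cds_features():
        # readthrough: decayed transposases carry internal stops, but family
        # assignment wants the full conceptual translation
        aa = translate_cds(genome, f, readthrough=True)
        if aa:
            proteome[f.feature_id] = aa
            by_id[f.feature_id] = f
    records = classify_transposases(proteome, is_reference,
                                    min_identity, min_coverage)
    for rec in records:
        f = by_id[rec.feature_id]
        rec.contig_id, rec.start, rec.end = f.contig_id, f.start, f.end
        irs = find_terminal_irs(genome.contigs[f.contig_id], (f.start, f.end),
                                window=ir_window, min_len=ir_min_len,
                                max_mismatch=ir_max_mismatch)
        rec.has_terminal_irs = irs is not None
    counts = {}
    for rec in records:
        counts[rec.family_id] = counts.get(rec.family_id, 0) + 1
    n_cds = len(genome.cds_features())
    return {
        "records": records,
        "family_counts": dict(sorted(counts.items())),
        "n_total_cds": n_cds,
        "n_te": len(records),
        "te_percent_of_cds": round(te_fraction(len(records), n_cds), 1)
        if n_cds else 0.0,
        "n_complete": sum(1 for r in records if r.completeness == "complete"),
    }
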