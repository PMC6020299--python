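"""Synthetic degraded-genome generator with full ground truth.

Emulates the evolutionary syndrome of a host-restricted symbiont genome:
an ancestral genome of ORFs, then a derived genome produced by gene
deletion, truncation-based pseudogenization (a configurable fraction caused
by transposase insertion into the gene), proliferation of a small number of
transposase families followed by per-copy decay, and clade-specific
substitution-rate acceleration on a fixed tree. Pileups carry a
sequencing-error floor plus a minority of true polymorphic sites.

All generators are deterministic under a fixed seed; every stochastic choice
is recorded in a TruthRecord so downstream calls can be scored exactly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .genome import AnnotatedGenome, Feature, revcomp
from .io import MultipleAlignment, PileupTable, PILEUP_COLUMNS
from .clock import SubstitutionModel, _Topology, _as_tree

log = logging.getLogger(__name__)

DEFAULT_CATEGORIES = (
    "amino_acid_synthesis", "energy_metabolism", "cell_wall_synthesis",
    "motility_chemotaxis", "dna_repair_recombination", "membrane_transport",
    "regulation_signaling", "stress_response", "carbohydrate_utilization",
    "protein_synthesis",
)

_STOPS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"

# codon usage for reverse translation: one codon per residue is enough here
_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "Q": "CAA",
    "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTG", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCT", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT", "X": "GCT",
}


def _random_bases(rng, n, gc):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(_BASES))[rng.choice(4, size=n, p=p)])


def _random_codons(rng, n, gc):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = []
    need = n
    while need > 0:
        draw = rng.choice(4, size=(need + 8, 3), p=p)
        chars = np.array(list(_BASES))[draw]
        codons = ["".join(row) for row in chars]
        out.extend(c for c in codons if c not in _STOPS)
        need = n - len(out)
    return "".join(out[:n])


# ---------------------------------------------------------------------------
# ancestor


def simulate_ancestor(n_genes: int, mean_gene_len: int = 900,
                      intergenic_len: int = 150, gc_frac: float = 0.40,
                      seed: int = 0, categories=DEFAULT_CATEGORIES,
                      category_blocks=None, category_run_mean: float = 8.0,
                      genome_id: str = "ancestor") -> AnnotatedGenome:
    """Single-contig ancestral genome of intact ORFs.

    Genes are ATG..stop ORFs with no internal stop, lengths scattered around
    ``mean_gene_len`` (nt). Functional-category tags are assigned in
    contiguous runs (operon-like clusters) so that category-protected blocks
    form contiguous genomic intervals; ``category_blocks`` — a list of
    (label, n_genes) — pins the first genes to fixed blocks, e.g. to build a
    protected gene cluster of known size.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    # category per gene
    tags = []
    if category_blocks:
        for label, k in category_blocks:
            tags.extend([label] * int(k))
    while len(tags) < n_genes:
        label = categories[rng.integers(len(categories))]
        run = 1 + rng.geometric(1.0 / category_run_mean)
        tags.extend([label] * run)
    tags = tags[:n_genes]

    pieces = [_random_bases(rng, intergenic_len, gc_frac)]
    features = []
    pos = intergenic_len
    for g in range(n_genes):
        n_codons = max(12, int(round(rng.normal(mean_gene_len / 3,
                                                mean_gene_len / 12))))
        orf = "ATG" + _random_codons(rng, n_codons - 2, gc_frac) + \
            _STOPS[rng.integers(3)]
        strand = "+" if rng.random() < 0.5 else "-"
        seq = orf if strand == "+" else revcomp(orf)
        start = pos + 1
        end = pos + len(seq)
        features.append(Feature(
            feature_id=f"g{g + 1:05d}", contig_id="chr1", start=start, end=end,
            strand=strand, kind="CDS", status="functional",
            product=f"protein {g + 1}", category_tags=frozenset({tags[g]})))
        pieces.append(seq)
        gap = max(20, int(round(rng.normal(intergenic_len, intergenic_len / 4))))
        pieces.append(_random_bases(rng, gap, gc_frac))
        pos = end + gap
    return AnnotatedGenome(genome_id, {"chr1": "".join(pieces)},
                           features).validate()


# ---------------------------------------------------------------------------
# degradation


@dataclass
class TEBurst:
    """One transposase-family expansion: n copies, then per-copy decay."""

    family_id: str
    n_copies: int
    decay_sub_rate: float = 0.05   # per-site substitution probability per copy
    decay_trunc_prob: float = 0.4  # probability a copy loses an end (and an IR)
    ir_len: int = 16
    source_protein: str | None = None  # default: bundled synthetic family rep


@dataclass
class DegradationParams:
    """Controls for degrading an ancestor into a derived symbiont-like genome."""

    deletion_frac: float = 0.0
    pseudo_frac: float = 0.0
    truncation_range: tuple = (0.1, 0.5)  # surviving fraction of a pseudogene
    te_bursts: list = field(default_factory=list)
    protected_blocks: tuple = ()  # category labels shielded from TE insertion
    pseudo_by_te_frac: float = 0.5  # fraction of pseudogenizations caused by TEs
    tsd_len: int = 4  # target-site duplication length
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("deletion_frac", "pseudo_frac", "pseudo_by_te_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.deletion_frac + self.pseudo_frac > 1.0:
            raise ValueError("deletion_frac + pseudo_frac > 1")
        lo, hi = self.truncation_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("truncation_range must satisfy 0 < lo <= hi < 1")
        for b in self.te_bursts:
            if b.n_copies < 0:
                raise ValueError("n_copies must be >= 0")


@dataclass
class TruthRecord:
    """Ground truth of a degradation run (JSON-serializable via asdict)."""

    seed: int
    gene_fates: dict = field(default_factory=dict)
    # gene_id -> {"fate": retained|deleted|pseudogenized,
    #             "truncation_frac": float|None, "by_te": bool}
    te_copies: list = field(default_factory=list)
    # {"copy_id", "family", "trunc_frac", "n_subs", "complete",
    #  "contig", "start", "end"}
    protected_intervals: list = field(default_factory=list)  # ancestor-space bp spans
    rate_multiplier: float | None = None
    polymorphic_sites: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _element_sequence(rng, burst: TEBurst, gc=0.45):
    """Ancestral element: IR + transposase ORF + reverse-complement IR."""
    if burst.source_protein is None:
        from .resources import default_is_reference
        refs = {r.family_id: r for r in default_is_reference()}
        if burst.family_id in refs:
            prot = refs[burst.family_id].representative_seq
        else:
            prot = "M" + "".join(np.array(list("ARNDCQEGHILKMFPSTWYV"))
                                 [rng.integers(0, 20, size=299)])
    else:
        prot = burst.source_protein
    orf = "".join(_CODON[a] for a in "M" + prot.lstrip("M")) + "TAA"
    ir = _random_bases(rng, burst.ir_len, gc)
    return ir, orf, revcomp(ir)


def _decay_copy(rng, ir_l, orf, ir_r, burst: TEBurst):
    """Apply point substitutions and possible end-truncation to one copy.

    Returns (seq, orf_lo, orf_hi, n_subs, trunc_frac, complete) where
    [orf_lo, orf_hi) is the frame-aligned surviving transposase ORF span
    within the decayed element (the annotated CDS; IRs stay outside it, as
    in real IS annotation). ``complete`` is the ground-truth state: no
    truncation and an IR pair still matching within 2 mismatches.
    """
    nl, no = len(ir_l), len(orf)
    seq = list(ir_l + orf + ir_r)
    n_subs = 0
    for i in range(len(seq)):
        if rng.random() < burst.decay_sub_rate:
            alt = _BASES[rng.integers(4)]
            if alt != seq[i]:
                seq[i] = alt
                n_subs += 1
    seq = "".join(seq)
    ir_mm = sum(a != b for a, b in zip(seq[:nl], revcomp(seq[-len(ir_r):])))
    trunc_frac = 1.0
    removed_prefix = 0
    L = len(seq)
    if rng.random() < burst.decay_trunc_prob:
        keep = rng.uniform(0.3, 0.8)
        trunc_frac = keep
        cut = int(round(L * keep))
        if rng.random() < 0.5:
            seq = seq[:cut]
        else:
            seq = seq[-cut:]
            removed_prefix = L - cut
    orf_lo = max(0, nl - removed_prefix)
    orf_hi = min(len(seq), nl + no - removed_prefix)
    # keep the CDS in the transposase reading frame after 5' loss
    in_orf_offset = orf_lo + removed_prefix - nl
    shift = (3 - in_orf_offset % 3) % 3
    orf_lo = min(orf_lo + shift, orf_hi)
    orf_hi = orf_lo + (orf_hi - orf_lo) - (orf_hi - orf_lo) % 3
    complete = trunc_frac == 1.0 and ir_mm <= 2
    return seq, orf_lo, orf_hi, n_subs, trunc_frac, complete


def degrade_genome(ancestor: AnnotatedGenome, params: DegradationParams):
    """Degrade an ancestor; returns (derived AnnotatedGenome, TruthRecord).

    Deleted genes are removed with their sequence; pseudogenized genes keep
    the recorded 5' fraction and are flagged; TE copies are inserted as
    annotated transposase CDS features with a target-site duplication, each
    independently decayed. Insertions avoid intergenic space inside
    protected category blocks. Raises when the unprotected intergenic space
    cannot host the requested number of copies.
    """
    rng = np.random.default_rng(params.rng_seed)
    truth = TruthRecord(seed=params.rng_seed)
    contig_id = next(iter(ancestor.contigs))
    if len(ancestor.contigs) != 1:
        raise ValueError("degrade_genome expects a single-contig ancestor")
    seq = ancestor.contigs[contig_id]
    feats = sorted(ancestor.features, key=lambda f: f.start)
    for a, b in zip(feats, feats[1:]):
        if b.start <= a.end:
            raise ValueError("ancestor features overlap; cannot degrade")

    # --- fates
    protected_cats_early = set(params.protected_blocks)
    by_te_budget = params.te_bursts[0].n_copies if params.te_bursts else 0
    fates = {}
    for f in feats:
        if f.kind != "CDS":
            fates[f.feature_id] = ("retained", None, False)
            continue
        if f.category_tags & protected_cats_early:
            # protected clusters model purifying selection: no deletion,
            # no pseudogenization, no insertions
            fates[f.feature_id] = ("retained", None, False)
            continue
        u = rng.random()
        if u < params.deletion_frac:
            fates[f.feature_id] = ("deleted", None, False)
        elif u < params.deletion_frac + params.pseudo_frac:
            tf = rng.uniform(*params.truncation_range)
            # protected clusters never receive insertions, so their
            # pseudogenizations are truncation-only
            by_te = (rng.random() < params.pseudo_by_te_frac
                     and by_te_budget > 0)
            if by_te:
                by_te_budget -= 1
            fates[f.feature_id] = ("pseudogenized", float(tf), by_te)
        else:
            fates[f.feature_id] = ("retained", None, False)

    # --- linear piece list: (sequence, feature-template or None, protected)
    protected_cats = set(params.protected_blocks)

    def is_protected(f):
        return bool(f.category_tags & protected_cats)

    pieces = []  # dicts: seq, feat (None for intergenic), protected, te_after
    cursor = 0
    prev_protected = False
    for f in feats:
        inter = seq[cursor:f.start - 1]
        pieces.append({"seq": inter, "feat": None,
                       "protected": prev_protected and is_protected(f),
                       "te_after": []})
        fate, tf, by_te = fates[f.feature_id]
        if fate == "deleted":
            pass
        else:
            gseq = seq[f.start - 1:f.end]
            feat = f
            if fate == "pseudogenized":
                keep = max(6, int(round(f.length * tf)))
                # truncate the 3' end in reading orientation
                gseq = gseq[:keep] if f.strand == "+" else gseq[-keep:]
                feat = f.with_status("pseudogene")
            piece = {"seq": gseq, "feat": feat, "protected": is_protected(f),
                     "te_after": []}
            if fate == "pseudogenized" and by_te:
                piece["te_after"].append("pending")
            pieces.append(piece)
        prev_protected = is_protected(f)
        cursor = f.end
    pieces.append({"seq": seq[cursor:], "feat": None, "protected": False,
                   "te_after": []})

    # protected ancestor-space intervals, for the truth record
    run_start = None
    pos = 0
    for f in feats:
        if is_protected(f):
            if run_start is None:
                run_start = f.start
            run_end = f.end
        else:
            if run_start is not None:
                truth.protected_intervals.append(
                    {"contig": contig_id, "start": run_start, "end": run_end})
                run_start = None
    if run_start is not None:
        truth.protected_intervals.append(
            {"contig": contig_id, "start": run_start, "end": run_end})

    # --- TE bursts
    te_plan = []  # (family, seq, n_subs, trunc_frac, complete, target)
    gene_sites = [p for p in pieces if p["te_after"]]
    site_cycle = iter(gene_sites)
    for bi, burst in enumerate(params.te_bursts):
        ir_l, orf, ir_r = _element_sequence(rng, burst)
        # copies that pseudogenized a gene: only drawn from the first burst
        n_in_genes = len(gene_sites) if bi == 0 else 0
        free_pieces = [p for p in pieces
                       if p["feat"] is None and not p["protected"]
                       and len(p["seq"]) > 2 * params.tsd_len]
        capacity = sum(len(p["seq"]) for p in free_pieces) // 20
        if burst.n_copies > n_in_genes + capacity:
            raise ValueError(
                f"insertion space exhausted: burst {burst.family_id} wants "
                f"{burst.n_copies} copies, capacity ~{n_in_genes + capacity}")
        weights = np.array([len(p["seq"]) for p in free_pieces], dtype=float)
        weights /= weights.sum()
        for c in range(burst.n_copies):
            cseq, orf_lo, orf_hi, n_subs, tf, complete = _decay_copy(
                rng, ir_l, orf, ir_r, burst)
            if c < n_in_genes:
                target = next(site_cycle)
                offset = None  # appended right after the truncated gene
            else:
                target = free_pieces[rng.choice(len(free_pieces), p=weights)]
                offset = int(rng.integers(params.tsd_len,
                                          len(target["seq"]) - params.tsd_len))
            te_plan.append({"family": burst.family_id, "seq": cseq,
                            "orf_lo": orf_lo, "orf_hi": orf_hi,
                            "n_subs": n_subs, "trunc_frac": tf,
                            "complete": complete, "target": target,
                            "offset": offset})

    # attach insertions to pieces
    for k, plan in enumerate(te_plan):
        plan["copy_id"] = f"te{k + 1:05d}"
        t = plan["target"]
        t.setdefault("inserts", []).append(plan)

    # --- rebuild derived genome
    out_seq = []
    out_feats = []
    pos = 0

    def emit(s):
        nonlocal pos
        out_seq.append(s)
        pos += len(s)

    def emit_te(plan):
        element_start = pos + 1
        cds_start = pos + plan["orf_lo"] + 1
        cds_end = pos + plan["orf_hi"]
        emit(plan["seq"])
        if cds_end - cds_start + 1 >= 9:
            out_feats.append(Feature(
                feature_id=plan["copy_id"], contig_id=contig_id,
                start=cds_start, end=cds_end, strand="+", kind="CDS",
                status="unknown",
                product=f"{plan['family']} family transposase",
                category_tags=frozenset({"mobile_element"})))
        truth.te_copies.append({
            "copy_id": plan["copy_id"], "family": plan["family"],
            "n_subs": plan["n_subs"], "trunc_frac": plan["trunc_frac"],
            "complete": plan["complete"], "contig": contig_id,
            "element_start": element_start, "element_end": pos,
            "start": cds_start, "end": cds_end})

    for p in pieces:
        inserts = sorted(p.get("inserts", []),
                         key=lambda x: (x["offset"] is None, x["offset"] or 0,
                                        x["copy_id"]))
        if p["feat"] is None:
            s = p["seq"]
            cur = 0
            for plan in inserts:
                off = plan["offset"]
                emit(s[cur:off])  # ends with the original target site
                emit_te(plan)
                emit(s[off - params.tsd_len:off])  # duplicated target site
                cur = off
            emit(s[cur:])
        else:
            f = p["feat"]
            start = pos + 1
            emit(p["seq"])
            out_feats.append(Feature(
                feature_id=f.feature_id, contig_id=contig_id, start=start,
                end=pos, strand=f.strand, kind=f.kind, status=f.status,
                product=f.product, category_tags=f.category_tags))
            for plan in inserts:  # TE that pseudogenized this gene
                emit_te(plan)

    for f in feats:
        fate, tf, by_te = fates[f.feature_id]
        truth.gene_fates[f.feature_id] = {
            "fate": fate if f.kind == "CDS" else "retained",
            "truncation_frac": tf, "by_te": by_te}

    derived = AnnotatedGenome(
        ancestor.genome_id + "_derived", {contig_id: "".join(out_seq)},
        out_feats, source="degrade_genome").validate()
    return derived, truth


def proteome_of(genome: AnnotatedGenome, status: str | None = "functional") -> dict:
    """Translate CDS features (default: functional only) to a proteome dict."""
    from .pseudogenes import translate_cds
    out = {}
    for f in genome.cds_features(status):
        aa = translate_cds(genome, f)
        if aa:
            out[f.feature_id] = aa
    return out


# ---------------------------------------------------------------------------
# sequence evolution on a tree


def random_ultrametric_tree(n_taxa: int, height: float, seed: int = 0,
                            labels=None) -> dendropy.Tree:
    """Random rooted ultrametric tree (coalescent-style random joins)."""
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_taxa)]
    merge_h = np.sort(rng.uniform(0.05, 1.0, size=n_taxa - 1))
    merge_h = merge_h / merge_h[-1] * height
    taxa = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nd.height = 0.0
        nodes.append(nd)
    for h in merge_h:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = dendropy.Node()
        parent.height = float(h)
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = parent.height - a.height
        b.edge.length = parent.height - b.height
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    return tree


def simulate_alignment(tree, model: SubstitutionModel, foreground_clade=None,
                       rate_multiplier: float = 1.0, n_sites: int = 1000,
                       seed: int = 0) -> MultipleAlignment:
    """Simulate i.i.d. sites down a rooted tree under a reversible model.

    Branches inside (and including the stem of) the foreground clade evolve
    at ``rate_multiplier`` times the background rate. Branch lengths on the
    tree are read as background expected substitutions per site.
    """
    if rate_multiplier <= 0:
        raise ValueError("rate_multiplier must be > 0")
    rng = np.random.default_rng(seed)
    t = _as_tree(tree)
    topo = _Topology(t)
    lengths = np.zeros(topo.n_nodes)
    for n in t.postorder_node_iter():
        i = topo.index[id(n)]
        if n.parent_node is not None:
            if n.edge.length is None or n.edge.length < 0:
                raise ValueError("tree must have non-negative branch lengths")
            lengths[i] = n.edge.length
    fg_nodes = set(topo.clade_nodes(set(foreground_clade))) \
        if foreground_clade else set()
    eff = lengths * np.array([rate_multiplier if i in fg_nodes else 1.0
                              for i in range(topo.n_nodes)])
    site_rates = model.gamma_rates()
    cat = rng.integers(len(site_rates), size=n_sites)
    states = np.empty((topo.n_nodes, n_sites), dtype=np.int64)
    root = topo.root
    states[root] = rng.choice(model.n_states, size=n_sites, p=model.pi)
    for i in reversed(topo.postorder):  # preorder
        if i == root:
            continue
        parent_states = states[topo.parent[i]]
        child = np.empty(n_sites, dtype=np.int64)
        for ci, rate in enumerate(site_rates):
            P = model.transition_matrices(np.array([eff[i] * rate]))[0]
            mask = cat == ci
            for s in range(model.n_states):
                m2 = mask & (parent_states == s)
                k = int(m2.sum())
                if k:
                    child[m2] = rng.choice(model.n_states, size=k, p=P[s])
        states[i] = child
    ids = []
    seqs = []
    lookup = np.array(list(model.states))
    for i in topo.leaves:
        ids.append(topo.labels[i])
        seqs.append("".join(lookup[states[i]]))
    return MultipleAlignment(ids, seqs,
                             "nucleotide" if model.alphabet == "nt" else "amino-acid")


# ---------------------------------------------------------------------------
# pileup


def simulate_pileup(genome: AnnotatedGenome, mean_depth: float,
                    error_rate: float, polymorphic_sites=(),
                    seed: int = 0) -> PileupTable:
    """Per-site read pileup: Poisson depth, binomial error floor, true SNPs.

    Non-polymorphic sites draw each non-reference base count from
    Binomial(depth, error_rate/3); a polymorphic site (pos, alt, freq) adds
    Binomial(depth, freq) reads of the stated alternate. Positions are
    1-based over the concatenated contigs.
    """
    rng = np.random.default_rng(seed)
    poly = {}
    for pos, alt, freq in polymorphic_sites:
        if not 0.0 < freq < 1.0:
            raise ValueError(f"polymorphic freq must be in (0,1): {freq}")
        poly[int(pos)] = (alt.upper(), float(freq))
    frames = []
    base_idx = {b: i for i, b in enumerate(_BASES)}
    for contig_id, seq in genome.contigs.items():
        L = len(seq)
        for pos in poly:
            if pos < 1 or pos > L:
                raise ValueError(f"polymorphic position {pos} outside contig "
                                 f"{contig_id} (length {L})")
        depth = rng.poisson(mean_depth, size=L)
        counts = np.zeros((L, 4), dtype=np.int64)
        ref = np.array([base_idx.get(b, 0) for b in seq])
        if error_rate > 0:
            for b in range(4):
                err = rng.binomial(depth, error_rate / 3)
                counts[:, b] += np.where(ref == b, 0, err)
        for pos, (alt, freq) in poly.items():
            i = pos - 1
            counts[i, base_idx[alt]] += rng.binomial(depth[i], freq)
        alt_total = counts.sum(axis=1)
        over = alt_total > depth
        if over.any():  # extreme draws: trim alternates to fit the depth
            for i in np.where(over)[0]:
                excess = alt_total[i] - depth[i]
                for b in np.argsort(-counts[i]):
                    take = min(excess, counts[i, b])
                    counts[i, b] -= take
                    excess -= take
            alt_total = counts.sum(axis=1)
        counts[np.arange(L), ref] = depth - alt_total
        frames.append(pd.DataFrame({
            "contig": contig_id, "pos": np.arange(1, L + 1),
            "ref": list(seq), "depth": depth,
            "A": counts[:, 0], "C": counts[:, 1],
            "G": counts[:, 2], "T": counts[:, 3]}))
    table = pd.concat(frames, ignore_index=True) if frames else None
    if table is None:
        return PileupTable()
    return PileupTable(table[PILEUP_COLUMNS])
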