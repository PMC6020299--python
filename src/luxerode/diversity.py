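"""Intra-sample diversity from per-site read pileups.

Computes the alternate-base frequency spectrum, classifies sites into
error-like (< 0.05% of per-site depth), intermediate, and polymorphic
(> 1% of per-site depth), and reports potential polymorphisms per kilobase.
Only the single majority alternate base per site is scored; the alternate
frequency is relative to the site's own depth (a literal per-site reading —
note that at modest depths the error threshold sits below one read, so
singleton alternates classify as intermediate rather than error-like).
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import PileupTable

log = logging.getLogger(__name__)

F_ERR = 0.0005   # alternate fraction below which a site reads as error-like
F_POLY = 0.01    # above which it reads as truly polymorphic

DEFAULT_BIN_EDGES = np.logspace(-4, 0, 33)


def site_frequencies(pileup: PileupTable) -> pd.DataFrame:
    """Per-site majority-alternate frequency records.

    Zero-depth rows are skipped (logged). alt_base is the highest-count
    non-reference base, ties broken in fixed order A < C < G < T;
    alt_freq = alt_count / depth.
    """
    t = pileup.table
    if not len(t):
        return pd.DataFrame(columns=["contig", "pos", "depth", "alt_base",
                                     "alt_count", "alt_freq"])
    zero = t["depth"] == 0
    if zero.any():
        log.info("site_frequencies: skipping %d zero-depth sites", int(zero.sum()))
        t = t[~zero]
    bases = ["A", "C", "G", "T"]
    counts = t[bases].to_numpy(dtype=np.int64)
    ref_idx = pd.Categorical(t["ref"].str.upper(), categories=bases).codes
    masked = counts.copy()
    rows = np.arange(len(t))
    known_ref = ref_idx >= 0
    masked[rows[known_ref], ref_idx[known_ref]] = -1  # exclude the reference base
    alt_idx = masked.argmax(axis=1)  # argmax takes the first max: A<C<G<T
    alt_count = masked[rows, alt_idx].clip(min=0)
    return pd.DataFrame({
        "contig": t["contig"].to_numpy(),
        "pos": t["pos"].to_numpy(),
        "depth": t["depth"].to_numpy(),
        "alt_base": np.array(bases)[alt_idx],
        "alt_count": alt_count,
        "alt_freq": alt_count / t["depth"].to_numpy(),
    })


def classify_sites(sites: pd.DataFrame, f_err: float = F_ERR,
                   f_poly: float = F_POLY) -> dict:
    """Partition nonzero-alternate sites into error-like / intermediate / polymorphic.

    frac_error_like = n_error_like / (number of nonzero-alternate sites);
    None when there are no such sites.
    """
    if not 0.0 < f_err < f_poly < 1.0:
        raise ValueError("need 0 < f_err < f_poly < 1")
    nz = sites[sites["alt_freq"] > 0] if len(sites) else sites
    n = len(nz)
    if n == 0:
        return {"n_error_like": 0, "n_intermediate": 0, "n_polymorphic": 0,
                "frac_error_like": None}
    freq = nz["alt_freq"].to_numpy()
    n_err = int((freq < f_err).sum())
    n_poly = int((freq > f_poly).sum())
    return {
        "n_error_like": n_err,
        "n_intermediate": n - n_err - n_poly,
        "n_polymorphic": n_poly,
        "frac_error_like": n_err / n,
    }


def polymorphism_rate(sites: pd.DataFrame, genome_length_bp: int,
                      f_poly: float = F_POLY) -> float:
    """Potential polymorphisms per kilobase of genome."""
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be > 0")
    n_poly = int((sites["alt_freq"] > f_poly).sum()) if len(sites) else 0
    return 1000.0 * n_poly / genome_length_bp


def spectrum(sites: pd.DataFrame, bin_edges=None) -> dict:
    """Histogram of nonzero alternate-base frequencies (the Fig-S1-style spectrum).

    Frequencies outside [edges[0], edges[-1]] are clamped into the end bins
    (logged). Bin counts sum to the number of nonzero-alternate sites.
    """
    edges = np.asarray(DEFAULT_BIN_EDGES if bin_edges is None else bin_edges,
                       dtype=float)
    if (np.diff(edges) <= 0).any():
        raise ValueError("bin edges must be strictly increasing")
    freq = sites[sites["alt_freq"] > 0]["alt_freq"].to_numpy() if len(sites) \
        else np.array([])
    n_out = int(((freq < edges[0]) | (freq > edges[-1])).sum())
    if n_out:
        log.info("spectrum: clamping %d out-of-range frequencies", n_out)
    clamped = np.clip(freq, edges[0], edges[-1])
    counts, _ = np.histogram(clamped, bins=edges)
    return {"bin_edges": edges.tolist(), "counts": counts.tolist(),
            "total_sites": int(len(freq))}


def diversity_report(pileup: PileupTable, genome_length_bp: int,
                     f_err: float = F_ERR, f_poly: float = F_POLY,
                     bin_edges=None) -> dict:
    """One-call summary: spectrum + site classes + per-kb polymorphism rate."""
    sites = site_frequencies(pileup)
    rep = {"classes": classify_sites(sites, f_err, f_poly),
           "spectrum": spectrum(sites, bin_edges),
           "polymorphisms_per_kb": round(
               polymorphism_rate(sites, genome_length_bp, f_poly), 4)}
    return rep
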