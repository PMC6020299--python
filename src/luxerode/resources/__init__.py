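"""Bundled reference fixtures.

The IS-family reference shipped here (synthetic_is_reference.faa/.tsv) is a
SYNTHETIC stand-in: one deterministically generated representative
transposase per IS family commonly censused in reduced genomes (IS5, IS982,
IS256, ISL3, Tn3, IS200/IS605, IS66, IS6, ISAs1), with realistic lengths but
random sequence content. It supports self-contained simulation and testing;
for real annotation, point the census at an ISfinder-derived FASTA/TSV with
the same columns.

Pathway and category fixtures (synthetic_pathways.tsv, enzyme labels) are
likewise synthetic emulations of amino-acid-synthesis pathway definitions.
"""
from __future__ import annotations

from importlib import resources as _res
from pathlib import Path

_FAMILY_LENGTHS = {
    "IS5": 330, "IS982": 290, "IS256": 400, "ISL3": 440, "Tn3": 520,
    "IS200_IS605": 150, "IS66": 500, "IS6": 230, "ISAs1": 370,
}

_AA20 = "ARNDCQEGHILKMFPSTWYV"


def _path(name: str) -> Path:
    return Path(_res.files(__package__) / name)


def build_synthetic_reference(seed: int = 20180626):
    """Deterministically generate the synthetic IS representative set.

    Returns (seqs: dict id->protein, meta: list of row dicts). Used once to
    produce the bundled files; kept so the fixture is reproducible from code.
    """
    import numpy as np
    rng = np.random.default_rng(seed)
    # roughly transposase-like composition (hydrophobic + charged enriched)
    comp = np.array([8.3, 5.6, 4.0, 5.4, 1.0, 3.9, 6.7, 7.0, 2.2, 6.0,
                     9.7, 5.9, 2.4, 3.9, 4.6, 6.5, 5.3, 1.1, 3.0, 7.5])
    comp = comp / comp.sum()
    seqs = {}
    meta = []
    for fam, length in _FAMILY_LENGTHS.items():
        aa = "".join(np.array(list(_AA20))[rng.choice(20, size=length - 1,
                                                      p=comp)])
        rid = f"{fam}_rep"
        seqs[rid] = "M" + aa
        meta.append({"family_id": fam, "representative_id": rid,
                     "full_length_aa": length, "ir_min_len": 10,
                     "ir_window": 100})
    return seqs, meta


def default_is_reference() -> list:
    """The bundled synthetic IS-family reference set."""
    from ..te import load_is_reference
    return load_is_reference(_path("synthetic_is_reference.faa"),
                             _path("synthetic_is_reference.tsv"))


def default_pathways() -> Path:
    """Path to the bundled synthetic amino-acid pathway definition TSV."""
    return _path("synthetic_pathways.tsv")
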