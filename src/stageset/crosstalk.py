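"""Ligand-receptor complementarity between two condition-selective sets.

The motivating biology: genes for secreted ligands up-regulated in one cell
population whose cognate receptors are up-regulated in the neighbouring
population indicate directed signalling — here, stem cell (germ, 9 dpp) to
niche (Sertoli, 9 dpp) communication.  Pairing is taken from an explicit
(ligand, receptor) table; a small demo table with classic niche axes
(vegfc-kdr, edn1-ednrb, bdnf-ntrk1, cxcl12-cxcr4, kitl-kit) ships with the
package.

The accompanying completeness statistic is this package's extension: given
the ligands of the table found in set A, it asks whether their receptors
land in set B more often than random placement over the universe would
give, via the upper hypergeometric tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .enrich import hypergeom_tail
from .io import PairTable

__all__ = ["CrosstalkResult", "find_crosstalk", "demo_pair_table"]


def demo_pair_table() -> PairTable:
    """The bundled demo (ligand, receptor) table."""
    text = (
        resources.files("stageset").joinpath("data/lr_pairs_demo.tsv").read_text("utf-8")
    )
    rows = []
    for ln in text.splitlines():
        if not ln.strip() or ln.startswith("#") or ln.startswith("ligand\t"):
            continue
        a, b = ln.split("\t")[:2]
        rows.append((a, b))
    return PairTable(rows=tuple(rows))


@dataclass(frozen=True)
class CrosstalkResult:
    hits: pd.DataFrame  # ligand_id, receptor_id, ligand_set, receptor_set, orientation
    stats: pd.DataFrame  # per orientation: n_candidates, n_hits, p_complete


def find_crosstalk(
    set_a: frozenset[str],
    label_a: str,
    set_b: frozenset[str],
    label_b: str,
    pairs: PairTable,
    universe: frozenset[str] | None = None,
) -> CrosstalkResult:
    """Complementary ligand-receptor pairs across two gene sets.

    Orientation "A->B": ligand in set A, receptor in set B (and likewise
    "B->A"); same-set pairs never count.  When a universe is given, each
    orientation gets a completeness p-value: of the table's receptors
    present in the universe (N draws would place them anywhere), those
    whose ligand sits in the sending set (n) are tested for landing in the
    receiving set (m members) k times, k = number of complete pairs.
    """
    if not pairs.rows:
        raise ValueError("empty ligand-receptor pair table")
    if label_a == label_b:
        raise ValueError("the two sets must carry distinct condition labels")
    hit_rows = []
    stat_rows = []
    for (send, s_label), (recv, r_label), orient in (
        ((set_a, label_a), (set_b, label_b), f"{label_a}->{label_b}"),
        ((set_b, label_b), (set_a, label_a), f"{label_b}->{label_a}"),
    ):
        candidates = [(l, r) for l, r in pairs.rows if l in send]
        k = 0
        for lig, rec in candidates:
            if rec in recv and rec not in send:
                hit_rows.append(
                    {
                        "ligand_id": lig,
                        "receptor_id": rec,
                        "ligand_set": s_label,
                        "receptor_set": r_label,
                        "orientation": orient,
                    }
                )
                k += 1
        row = {"orientation": orient, "n_candidates": len(candidates), "n_hits": k}
        if universe:
            receptors = {r for l, r in candidates if r in universe}
            N = len(universe)
            m = len(recv & universe)
            n = len(receptors)
            kk = min(k, min(m, n))
            row["p_complete"] = hypergeom_tail(N, m, n, kk, "upper")
        stat_rows.append(row)
    hits = pd.DataFrame.from_records(
        hit_rows,
        columns=["ligand_id", "receptor_id", "ligand_set", "receptor_set", "orientation"],
    )
    return CrosstalkResult(hits=hits, stats=pd.DataFrame.from_records(stat_rows))
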