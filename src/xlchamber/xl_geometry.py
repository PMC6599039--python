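"""Restraint geometry: distances, satisfaction, and foldedness statistics.

The amine-reactive cross-linker (DSS) joins lysines whose C-alpha atoms lie
within about 32 A of each other, accounting for side-chain length and
backbone flexibility. Mapped restraints are therefore classified as
satisfied when the C-alpha–C-alpha distance is at or below the cutoff
(exactly 32.0 A by default; the boundary counts as satisfied).

The foldedness of a substrate is quantified against the *background* of all
linkable lysine pairs in a reference structure: if a fraction of those pairs
exceeds the linker limit, how surprising is it to observe only k violations
among the n links actually detected? Under uniform sampling without
replacement that tail probability is hypergeometric, computed exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .crosslinks import MappedRestraint
from .structure_io import MissingAtomError, ResidueRef, StructureModel

__all__ = [
    "DEFAULT_CUTOFF",
    "RestraintReport",
    "BackgroundPairSet",
    "ca_distance",
    "evaluate_restraints",
    "background_pairs",
    "compatibility_pvalue",
    "write_report_tsv",
    "write_report_json",
]

#: DSS C-alpha to C-alpha limit in Angstrom.
DEFAULT_CUTOFF = 32.0


def ca_distance(model: StructureModel, a: ResidueRef, b: ResidueRef) -> float:
    """Euclidean C-alpha–C-alpha distance in Angstrom (symmetric in a, b).

    For hetero groups the residue's reference atom stands in for C-alpha.
    Raises :class:`MissingAtomError` if either residue lacks one.
    """
    return float(np.linalg.norm(model.ca_coord(a) - model.ca_coord(b)))


@dataclass
class RestraintReport:
    """Per-restraint distances and satisfaction at a cutoff, with counts."""

    cutoff: float
    rows: list[MappedRestraint]
    n_unmapped: int = 0

    @property
    def n_total(self) -> int:
        return len(self.rows) + self.n_unmapped

    @property
    def n_satisfied(self) -> int:
        return sum(1 for r in self.rows if r.distance <= self.cutoff)

    @property
    def n_violated(self) -> int:
        return sum(1 for r in self.rows if r.distance > self.cutoff)

    def satisfied(self, r: MappedRestraint) -> bool:
        return r.distance <= self.cutoff

    def summary(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "n_total": self.n_total,
            "n_mapped": len(self.rows),
            "n_satisfied": self.n_satisfied,
            "n_violated": self.n_violated,
            "n_unmapped": self.n_unmapped,
            "n_surrogate_anchored": sum(
                1 for r in self.rows if r.surrogate_a or r.surrogate_b
            ),
        }


def evaluate_restraints(
    model: StructureModel,
    restraints: Sequence[MappedRestraint],
    cutoff: float = DEFAULT_CUTOFF,
    surrogate_slack: float = 0.0,
) -> RestraintReport:
    """Classify every mapped restraint against the distance cutoff.

    Distances are (re)computed on this model from the stored anchors, so a
    report is always consistent with the model it is evaluated on.
    Restraints whose anchors cannot be resolved are counted in
    ``n_unmapped``, never silently dropped.

    ``surrogate_slack`` adds s Angstrom of allowance per surrogate-anchored
    side (default 0: surrogate anchors face the same limit as real ones).
    """
    rows: list[MappedRestraint] = []
    n_unmapped = 0
    for r in restraints:
        try:
            d = ca_distance(model, r.anchor_a, r.anchor_b)
        except MissingAtomError:
            n_unmapped += 1
            continue
        slack = surrogate_slack * (int(r.surrogate_a) + int(r.surrogate_b))
        rows.append(
            MappedRestraint(
                link=r.link,
                anchor_a=r.anchor_a,
                anchor_b=r.anchor_b,
                surrogate_a=r.surrogate_a,
                surrogate_b=r.surrogate_b,
                distance=d - slack,
            )
        )
    return RestraintReport(cutoff=cutoff, rows=rows, n_unmapped=n_unmapped)


@dataclass
class BackgroundPairSet:
    """All unordered pairs of (by default) lysines in one chain."""

    chain_id: str
    residue_filter: str
    cutoff: float
    pairs: list[tuple[ResidueRef, ResidueRef, float]] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_exceeding(self) -> int:
        return sum(1 for *_refs, d in self.pairs if d > self.cutoff)


def background_pairs(
    model: StructureModel,
    chain_id: str,
    residue_filter: str = "LYS",
    cutoff: float = DEFAULT_CUTOFF,
) -> BackgroundPairSet:
    """Enumerate all unordered pairs of resolved residues of one type.

    Only residues with a resolved C-alpha enter the population (the linker
    can only be mapped onto modelled residues); the protein N-terminal amine
    is not counted as a linkable site. Fewer than two matching residues
    yields an empty set, not an error.
    """
    matching = [
        r.ref
        for r in model.residues(chain_id)
        if r.ref.resname == residue_filter and r.ca is not None
    ]
    out = BackgroundPairSet(chain_id=chain_id, residue_filter=residue_filter, cutoff=cutoff)
    for i in range(len(matching)):
        for j in range(i + 1, len(matching)):
            d = ca_distance(model, matching[i], matching[j])
            out.pairs.append((matching[i], matching[j], d))
    return out


def compatibility_pvalue(
    n_pairs: int, n_exceeding: int, n_observed: int, k_violations: int
) -> float:
    """Exact lower-tail probability of seeing at most k violating links.

    Model: the n_observed detected links are drawn uniformly without
    replacement from the n_pairs possible pairs, of which n_exceeding
    violate the distance limit. A small P(X <= k) means the detected links
    avoid the violating pairs more than chance allows — evidence that the
    cross-linked molecule is folded like the reference structure rather
    than flexible.
    """
    if not (0 <= n_exceeding <= n_pairs):
        raise ValueError("need 0 <= n_exceeding <= n_pairs")
    if not (0 <= k_violations <= n_observed <= n_pairs):
        raise ValueError("need 0 <= k_violations <= n_observed <= n_pairs")
    return float(hypergeom.cdf(k_violations, n_pairs, n_exceeding, n_observed))


# ---------------------------------------------------------------------------
# report output
# ---------------------------------------------------------------------------

def write_report_tsv(report: RestraintReport, path: str | Path) -> None:
    rows = []
    for r in report.rows:
        rows.append(
            {
                "protein_a": r.link.protein_a,
                "pos_a": r.link.pos_a,
                "protein_b": r.link.protein_b,
                "pos_b": r.link.pos_b,
                "anchor_a": str(r.anchor_a),
                "anchor_b": str(r.anchor_b),
                "surrogate_a": r.surrogate_a,
                "surrogate_b": r.surrogate_b,
                "distance": round(r.distance, 3),
                "satisfied": report.satisfied(r),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "protein_a", "pos_a", "protein_b", "pos_b",
            "anchor_a", "anchor_b", "surrogate_a", "surrogate_b",
            "distance", "satisfied",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_report_json(
    report: RestraintReport,
    path: str | Path,
    extra: dict | None = None,
) -> None:
    payload = report.summary()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
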