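"""Cross-link tables and their resolution onto structure anchors.

Identified lysine–lysine cross-links arrive as pLink2-style CSV reports.
This module parses them into :class:`CrossLink` records (one per unique
residue pair), and maps each record onto concrete anchor atoms of a
:class:`~xlchamber.structure_io.StructureModel` through a :class:`ChainMap`
that knows which chain(s) carry each protein and any residue-number offset
(e.g. purification-tag offsets).

Residues that fall in disordered, unmodelled tails are re-anchored on the
nearest resolved residue (surrogate anchor), which for chaperonin termini is
the last ordered residue of the tail.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .structure_io import (
    NoAnchorError,
    ResidueRef,
    StructureModel,
    surrogate_anchor,
)

__all__ = [
    "CrossLink",
    "ChainMap",
    "MappedRestraint",
    "SchemaError",
    "MappingError",
    "parse_plink",
    "map_restraint",
    "map_all",
    "write_links_tsv",
    "read_links_tsv",
]


class SchemaError(ValueError):
    """The cross-link table lacks required columns."""


class MappingError(KeyError):
    """A protein in a cross-link is absent from the chain map."""


@dataclass(frozen=True)
class CrossLink:
    """One identified residue–residue cross-link (unique residue pair)."""

    protein_a: str
    pos_a: int
    protein_b: str
    pos_b: int
    score: float = math.nan
    source_row: int = -1

    def __post_init__(self) -> None:
        if self.pos_a < 1 or self.pos_b < 1:
            raise ValueError("cross-link positions are 1-based and must be >= 1")

    @property
    def link_class(self) -> Literal["intra", "inter"]:
        return "intra" if self.protein_a == self.protein_b else "inter"

    def pair_key(self) -> tuple[tuple[str, int], tuple[str, int]]:
        a, b = (self.protein_a, self.pos_a), (self.protein_b, self.pos_b)
        return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ChainMapEntry:
    chains: tuple[str, ...]
    offset: int = 0  # model resnum = table position + offset


class ChainMap:
    """Protein name -> (chain ids in the structure, residue-number offset).

    One protein may map to several chains (two copies of each chaperonin
    subunit, one per ring). Offsets absorb construct-tag numbering shifts
    and may be negative.
    """

    def __init__(self, entries: dict[str, ChainMapEntry | tuple] | None = None):
        self._entries: dict[str, ChainMapEntry] = {}
        for name, entry in (entries or {}).items():
            if not isinstance(entry, ChainMapEntry):
                chains, offset = entry
                if isinstance(chains, str):
                    chains = (chains,)
                entry = ChainMapEntry(tuple(chains), int(offset))
            self._entries[name] = entry

    def __contains__(self, protein: str) -> bool:
        return protein in self._entries

    def __getitem__(self, protein: str) -> ChainMapEntry:
        try:
            return self._entries[protein]
        except KeyError:
            raise MappingError(f"protein {protein!r} not in chain map") from None

    def proteins(self) -> list[str]:
        return list(self._entries)

    def validate(self, model: StructureModel) -> None:
        for name, entry in self._entries.items():
            for cid in entry.chains:
                if cid not in model:
                    raise MappingError(f"chain {cid!r} (protein {name!r}) not in model")


@dataclass
class MappedRestraint:
    """A cross-link resolved onto anchor residues of a specific model."""

    link: CrossLink
    anchor_a: ResidueRef
    anchor_b: ResidueRef
    surrogate_a: bool
    surrogate_b: bool
    distance: float = math.nan  # Angstrom, C-alpha to C-alpha

    @property
    def mapped(self) -> bool:
        return math.isfinite(self.distance)


# ---------------------------------------------------------------------------
# pLink-style CSV parsing
# ---------------------------------------------------------------------------

# column aliases for the flat residue-pair dialect (case/underscore tolerant)
_ALIASES = {
    "protein_a": {"protein_1", "protein1", "protein_a", "proteina", "prot1", "prota"},
    "pos_a": {"position_1", "position1", "pos_1", "pos1", "abspos1", "abspos_1",
              "position_a", "posa", "residue_1", "residue1"},
    "protein_b": {"protein_2", "protein2", "protein_b", "proteinb", "prot2", "protb"},
    "pos_b": {"position_2", "position2", "pos_2", "pos2", "abspos2", "abspos_2",
              "position_b", "posb", "residue_2", "residue2"},
    "score": {"score", "svm_score", "best_score", "q_value", "qvalue", "q-value",
              "evalue", "e_value", "fdr"},
}

# "sp|Q9BVC4|LST8_HUMAN (215)-sp|P40227|TCPZ_HUMAN (5)/" (pLink2 peptides dialect)
_PLINK_PAIR_RE = re.compile(
    r"(?P<prot_a>[^()\-/]+?)\s*\((?P<pos_a>\d+)\)\s*-\s*(?P<prot_b>[^()/]+?)\s*\((?P<pos_b>\d+)\)"
)


def _norm(col: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", col.strip().lower()).strip("_")


def _clean_protein(token: str) -> str:
    token = token.strip().strip("/")
    # keep a readable name out of "sp|ACC|NAME"-style tokens
    if "|" in token:
        parts = [p for p in token.split("|") if p]
        token = parts[-1]
    return token.strip()


def parse_plink(path: str | Path, score_threshold: float | None = None) -> list[CrossLink]:
    """Parse a pLink2-style cross-link CSV into unique residue-pair records.

    Two dialects are sniffed from the header:

    * a flat table with protein/position columns for both sides
      (``Protein_1, Position_1, Protein_2, Position_2[, Score]``);
    * the pLink2 peptide report, where the ``Proteins`` column encodes the
      pair as ``NAME (pos)-NAME (pos)``.

    Peptide-level rows collapse to unique residue pairs keeping the best
    (numerically smallest, pLink scores are E-value-like) score. Self-links
    (a residue linked to itself) are dropped. FDR filtering is assumed done
    upstream; ``score_threshold`` optionally drops rows with score above it.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.columns.size == 0:
        return []
    norm_cols = {_norm(c): c for c in df.columns}

    def find(field: str) -> str | None:
        for alias in _ALIASES[field]:
            if alias in norm_cols:
                return norm_cols[alias]
        return None

    cols = {f: find(f) for f in ("protein_a", "pos_a", "protein_b", "pos_b")}
    links: list[CrossLink] = []
    if all(cols.values()):
        score_col = find("score")
        for i, row in df.iterrows():
            score = float(row[score_col]) if score_col else math.nan
            links.append(
                CrossLink(
                    protein_a=_clean_protein(str(row[cols["protein_a"]])),
                    pos_a=int(row[cols["pos_a"]]),
                    protein_b=_clean_protein(str(row[cols["protein_b"]])),
                    pos_b=int(row[cols["pos_b"]]),
                    score=score,
                    source_row=int(i),
                )
            )
    elif "proteins" in norm_cols:
        score_col = find("score")
        pcol = norm_cols["proteins"]
        for i, row in df.iterrows():
            m = _PLINK_PAIR_RE.search(str(row[pcol]))
            if m is None:
                continue
            score = float(row[score_col]) if score_col else math.nan
            links.append(
                CrossLink(
                    protein_a=_clean_protein(m["prot_a"]),
                    pos_a=int(m["pos_a"]),
                    protein_b=_clean_protein(m["prot_b"]),
                    pos_b=int(m["pos_b"]),
                    score=score,
                    source_row=int(i),
                )
            )
    else:
        missing = [f for f, c in cols.items() if c is None]
        raise SchemaError(
            f"{path.name}: no recognised cross-link columns; "
            f"missing {missing} and no 'Proteins' column"
        )

    if score_threshold is not None:
        links = [l for l in links if not (l.score > score_threshold)]

    # collapse duplicate residue pairs, best (smallest) score wins; drop self-links
    best: dict[tuple, CrossLink] = {}
    for link in links:
        if link.protein_a == link.protein_b and link.pos_a == link.pos_b:
            continue
        key = link.pair_key()
        prev = best.get(key)
        if prev is None or (math.isfinite(link.score) and not link.score >= prev.score):
            best[key] = link
    return sorted(best.values(), key=lambda l: l.source_row)


# ---------------------------------------------------------------------------
# mapping onto a structure
# ---------------------------------------------------------------------------

def _anchor(model: StructureModel, chain_id: str, pos: int, offset: int) -> tuple[ResidueRef, bool]:
    return surrogate_anchor(model, chain_id, pos + offset)


def map_restraint(
    link: CrossLink,
    cmap: ChainMap,
    model: StructureModel,
    ambiguity: Literal["min_distance", "enumerate"] = "min_distance",
) -> list[MappedRestraint]:
    """Resolve one cross-link onto anchor atoms of the model.

    Homo-oligomer ambiguity (a protein present as several chains) yields one
    candidate restraint per unordered chain pairing; under ``min_distance``
    only the pairing with the smallest C-alpha distance is returned (the
    most favourable, i.e. satisfiable, assignment), under ``enumerate`` all
    are. For a cross-copy pairing the two residue-to-chain orientations are
    both evaluated and the shorter one kept, so each unordered chain pair
    contributes exactly once.
    """
    ea, eb = cmap[link.protein_a], cmap[link.protein_b]
    candidates: list[MappedRestraint] = []
    seen_pairs: set[frozenset[str]] = set()
    no_anchor_errors: list[Exception] = []
    for ca_id in ea.chains:
        for cb_id in eb.chains:
            pair = frozenset((ca_id, cb_id))
            if pair in seen_pairs:
                continue
            seen_pairs.add(pair)
            orientations = [(ca_id, cb_id)]
            if ca_id != cb_id and link.protein_a == link.protein_b:
                orientations.append((cb_id, ca_id))
            best: MappedRestraint | None = None
            for c1, c2 in orientations:
                try:
                    ref_a, sur_a = _anchor(model, c1, link.pos_a, ea.offset)
                    ref_b, sur_b = _anchor(model, c2, link.pos_b, eb.offset)
                except (NoAnchorError, KeyError) as exc:
                    no_anchor_errors.append(exc)
                    continue
                d = float(np.linalg.norm(model.ca_coord(ref_a) - model.ca_coord(ref_b)))
                r = MappedRestraint(link, ref_a, ref_b, sur_a, sur_b, distance=d)
                if best is None or r.distance < best.distance:
                    best = r
            if best is not None:
                candidates.append(best)
    if not candidates:
        if no_anchor_errors:
            raise NoAnchorError(
                f"no candidate chain of {link.protein_a}/{link.protein_b} has resolved residues"
            )
        raise MappingError(f"no candidate chain pairing for link {link}")
    candidates.sort(key=lambda r: (r.distance, r.anchor_a.key(), r.anchor_b.key()))
    if ambiguity == "min_distance":
        return [candidates[0]]
    if ambiguity == "enumerate":
        return candidates
    raise ValueError(f"ambiguity must be min_distance or enumerate, got {ambiguity!r}")


def map_all(
    links: Iterable[CrossLink],
    cmap: ChainMap,
    model: StructureModel,
    ambiguity: Literal["min_distance", "enumerate"] = "min_distance",
    strict: bool = False,
) -> tuple[list[MappedRestraint], list[CrossLink]]:
    """Map many links; returns (restraints, unmappable links).

    With ``strict=True`` mapping errors raise instead of being collected.
    """
    restraints: list[MappedRestraint] = []
    unmapped: list[CrossLink] = []
    for link in links:
        try:
            restraints.extend(map_restraint(link, cmap, model, ambiguity))
        except (MappingError, NoAnchorError):
            if strict:
                raise
            unmapped.append(link)
    return restraints, unmapped


# ---------------------------------------------------------------------------
# round-trippable link TSV
# ---------------------------------------------------------------------------

_LINK_COLUMNS = ["protein_a", "pos_a", "protein_b", "pos_b", "link_class", "score", "source_row"]


def write_links_tsv(links: Sequence[CrossLink], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "protein_a": l.protein_a,
                "pos_a": l.pos_a,
                "protein_b": l.protein_b,
                "pos_b": l.pos_b,
                "link_class": l.link_class,
                "score": l.score,
                "source_row": l.source_row,
            }
            for l in links
        ],
        columns=_LINK_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_links_tsv(path: str | Path) -> list[CrossLink]:
    df = pd.read_csv(path, sep="\t")
    return [
        CrossLink(
            protein_a=str(r.protein_a),
            pos_a=int(r.pos_a),
            protein_b=str(r.protein_b),
            pos_b=int(r.pos_b),
            score=float(r.score),
            source_row=int(r.source_row),
        )
        for r in df.itertuples(index=False)
    ]
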