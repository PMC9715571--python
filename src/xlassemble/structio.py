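"""Coordinate-model I/O and protein-name-to-chain residue mapping.

Structures are stored as flat, file-ordered lists of atom records in author
numbering (the numbering as deposited).  Full-length sequence numbering —
the convention crosslink tables use — exists only at the :class:`ChainMap`
boundary, which translates ``(protein name, full-length residue)`` into
``(chain id, author residue)`` addresses, including the ambiguous case of a
homodimer where one protein name maps to two chains.

Parsing and writing of PDB / mmCIF goes through gemmi; this layer fixes the
conventions the rest of the package relies on: first model only, highest-
occupancy alternate conformer (first seen on ties), hydrogens and waters
dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import yaml

logger = logging.getLogger(__name__)

_WATER = {"HOH", "WAT", "DOD", "H2O"}


@dataclass(frozen=True)
class AtomRecord:
    chain_id: str
    res_seq: int
    ins_code: str  # "" when absent
    res_name: str
    atom_name: str
    element: str
    pos: tuple[float, float, float]
    occupancy: float = 1.0
    b_factor: float = 0.0

    @property
    def residue_address(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.ins_code)

    @property
    def address(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.res_seq, self.ins_code, self.atom_name)


@dataclass
class StructureModel:
    """An ordered collection of atoms; iteration order is file order."""

    atoms: list[AtomRecord]
    title: str = ""
    source_format: str = "pdb"

    def __post_init__(self) -> None:
        seen = set()
        for a in self.atoms:
            if a.address in seen:
                raise ValueError(f"duplicate atom address {a.address}")
            seen.add(a.address)
            if not np.all(np.isfinite(a.pos)):
                raise ValueError(f"non-finite coordinates at {a.address}")

    # ---- queries -----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms], dtype=float)

    @property
    def chain_ids(self) -> list[str]:
        """Chain identifiers in first-appearance order."""
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def atom(self, chain_id: str, res_seq: int, atom_name: str,
             ins_code: str = "") -> AtomRecord | None:
        return self._index().get((chain_id, res_seq, ins_code, atom_name))

    def ca_coord(self, chain_id: str, res_seq: int,
                 ins_code: str = "") -> np.ndarray | None:
        a = self.atom(chain_id, res_seq, "CA", ins_code)
        return None if a is None else np.asarray(a.pos, dtype=float)

    def ca_residues(self, chain_id: str) -> dict[int, np.ndarray]:
        """Author residue number -> Calpha coordinate, for one chain."""
        out: dict[int, np.ndarray] = {}
        for a in self.atoms:
            if a.chain_id == chain_id and a.atom_name == "CA":
                out.setdefault(a.res_seq, np.asarray(a.pos, dtype=float))
        return out

    def ca_coords(self, chains: Sequence[str] | None = None) -> np.ndarray:
        sel = None if chains is None else set(chains)
        pts = [a.pos for a in self.atoms
               if a.atom_name == "CA" and (sel is None or a.chain_id in sel)]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def residue_ranges(self) -> dict[str, tuple[int, int]]:
        out: dict[str, tuple[int, int]] = {}
        for a in self.atoms:
            lo, hi = out.get(a.chain_id, (a.res_seq, a.res_seq))
            out[a.chain_id] = (min(lo, a.res_seq), max(hi, a.res_seq))
        return out

    def _index(self) -> dict:
        idx = getattr(self, "_addr_index", None)
        if idx is None:
            idx = {a.address: a for a in self.atoms}
            object.__setattr__(self, "_addr_index", idx)
        return idx

    # ---- derivation --------------------------------------------------

    def select(self, chains: Iterable[str] | None = None,
               residue_ranges: dict[str, Sequence[tuple[int, int]]] | None = None,
               atom_names: Iterable[str] | None = None) -> "StructureModel":
        """Subset by chain, residue range(s) per chain, and/or atom name."""
        chains = None if chains is None else set(chains)
        atom_names = None if atom_names is None else set(atom_names)
        kept = []
        for a in self.atoms:
            if chains is not None and a.chain_id not in chains:
                continue
            if atom_names is not None and a.atom_name not in atom_names:
                continue
            if residue_ranges is not None:
                ranges = residue_ranges.get(a.chain_id)
                if ranges is None or not any(lo <= a.res_seq <= hi
                                             for lo, hi in ranges):
                    continue
            kept.append(a)
        return StructureModel(kept, title=self.title,
                              source_format=self.source_format)

    def atom_indices(self, chains: Iterable[str] | None = None,
                     residue_ranges: dict[str, Sequence[tuple[int, int]]] | None = None
                     ) -> np.ndarray:
        """Indices into ``atoms`` matching a chain/residue-range selection."""
        chains = None if chains is None else set(chains)
        out = []
        for i, a in enumerate(self.atoms):
            if chains is not None and a.chain_id not in chains:
                continue
            if residue_ranges is not None:
                ranges = residue_ranges.get(a.chain_id)
                if ranges is None or not any(lo <= a.res_seq <= hi
                                             for lo, hi in ranges):
                    continue
            out.append(i)
        return np.array(out, dtype=int)

    def subset(self, indices: Sequence[int]) -> "StructureModel":
        return StructureModel([self.atoms[i] for i in indices],
                              title=self.title, source_format=self.source_format)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    chains: Iterable[str] | None = None) -> "StructureModel":
        """Apply ``x -> R x + t`` to all atoms (or only to named chains)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        sel = None if chains is None else set(chains)
        new_atoms = []
        for a in self.atoms:
            if sel is None or a.chain_id in sel:
                p = R @ np.asarray(a.pos) + t
                new_atoms.append(replace(a, pos=(float(p[0]), float(p[1]),
                                                 float(p[2]))))
            else:
                new_atoms.append(a)
        return StructureModel(new_atoms, title=self.title,
                              source_format=self.source_format)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _detect_format(path: Path, format_hint: str | None) -> str:
    if format_hint:
        fmt = format_hint.lower()
        if fmt not in ("pdb", "mmcif", "cif"):
            raise ValueError(f"unknown format hint {format_hint!r}")
        return "mmcif" if fmt in ("mmcif", "cif") else "pdb"
    suffix = path.suffix.lower()
    return "mmcif" if suffix in (".cif", ".mmcif") else "pdb"


def read_structure(path, format_hint: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF coordinate file into a :class:`StructureModel`.

    Multi-model files keep the first model only (logged).  Alternate
    locations resolve to the highest-occupancy conformer, first-seen on
    ties.  Hydrogens/deuteriums and waters are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format_hint)
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    if len(st) > 1:
        logger.warning("%s: %d models present, keeping the first", path, len(st))
    model = st[0]

    # alt-loc resolution: best occupancy per atom address, first-seen on ties
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for chain in model:
        for res in chain:
            if res.name in _WATER:
                continue
            icode = res.seqid.icode.strip()
            for atom in res:
                elem = atom.element.name.upper()
                if elem in ("H", "D"):
                    continue
                addr = (chain.name, res.seqid.num, icode, atom.name)
                rec = AtomRecord(
                    chain_id=chain.name, res_seq=res.seqid.num, ins_code=icode,
                    res_name=res.name, atom_name=atom.name, element=elem,
                    pos=(atom.pos.x, atom.pos.y, atom.pos.z),
                    occupancy=float(atom.occ), b_factor=float(atom.b_iso))
                if addr not in best:
                    best[addr] = rec
                    order.append(addr)
                elif rec.occupancy > best[addr].occupancy:
                    best[addr] = rec
    atoms = [best[a] for a in order]
    if not atoms:
        raise ValueError(f"{path}: no atoms after filtering")
    title = st.name or path.stem
    return StructureModel(atoms, title=title, source_format=fmt)


def write_structure(model: StructureModel, path, format: str | None = None) -> None:
    """Write a model as PDB (fixed-width, 3-decimal coordinates) or mmCIF."""
    if model.n_atoms == 0:
        raise ValueError("refusing to write an empty model")
    path = Path(path)
    fmt = _detect_format(path, format)
    st = gemmi.Structure()
    st.name = model.title or "model"
    gm = gemmi.Model("1")
    chain = None
    residue = None
    for a in model.atoms:
        if chain is None or chain.name != a.chain_id:
            chain = gemmi.Chain(a.chain_id)
            gm.add_chain(chain)
            chain = gm[-1]
            residue = None
        if (residue is None or residue.seqid.num != a.res_seq
                or residue.seqid.icode.strip() != a.ins_code
                or residue.name != a.res_name):
            residue = gemmi.Residue()
            residue.name = a.res_name
            residue.seqid = gemmi.SeqId(a.res_seq, a.ins_code or " ")
            chain.add_residue(residue)
            residue = chain[-1]
        atom = gemmi.Atom()
        atom.name = a.atom_name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(*a.pos)
        atom.occ = a.occupancy
        atom.b_iso = a.b_factor
        residue.add_atom(atom)
    st.add_model(gm)
    st.setup_entities()
    if fmt == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Chain mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainSpan:
    """One mapped segment: protein name + full-length range -> a chain."""

    protein: str
    chain_id: str
    offset: int  # author res_seq = full-length residue + offset
    first: int   # full-length numbering, inclusive
    last: int

    def contains(self, full_length_residue: int) -> bool:
        return self.first <= full_length_residue <= self.last


class ChainMap:
    """Translates (protein name, full-length residue) to chain addresses.

    A protein may map to several chains (homodimer copies); ``map_residue``
    then returns every candidate address.  Residues outside every mapped
    range return an empty list — "unmapped" is a status, not an error, so
    crosslinks to disordered or absent regions can be excluded with
    accounting.
    """

    def __init__(self, spans: Sequence[ChainSpan], strict: bool = False):
        self.spans = list(spans)
        self.strict = strict
        self._validate()

    def _validate(self) -> None:
        by_chain: dict[str, list[tuple[int, int]]] = {}
        for s in self.spans:
            if s.first > s.last:
                raise ValueError(f"invalid range {s.first}-{s.last} for {s.protein}")
            author = (s.first + s.offset, s.last + s.offset)
            for lo, hi in by_chain.get(s.chain_id, []):
                if author[0] <= hi and lo <= author[1]:
                    raise ValueError(
                        f"overlapping author ranges on chain {s.chain_id}")
            by_chain.setdefault(s.chain_id, []).append(author)

    @property
    def proteins(self) -> list[str]:
        out: list[str] = []
        for s in self.spans:
            if s.protein not in out:
                out.append(s.protein)
        return out

    def map_residue(self, protein_name: str,
                    full_length_residue: int) -> list[tuple[str, int]]:
        """All (chain_id, author res_seq) addresses for a full-length residue.

        Empty list means unmapped.  With ``strict=True`` an unknown protein
        name raises instead of returning unmapped.
        """
        known = False
        out = []
        for s in self.spans:
            if s.protein != protein_name:
                continue
            known = True
            if s.contains(full_length_residue):
                out.append((s.chain_id, full_length_residue + s.offset))
        if self.strict and not known:
            raise KeyError(f"unknown protein {protein_name!r}")
        return out

    # ---- config round trip ------------------------------------------

    @classmethod
    def from_dict(cls, data: dict, strict: bool = False) -> "ChainMap":
        spans = []
        for protein, entries in data.get("proteins", {}).items():
            for e in entries:
                first, last = e["range"]
                spans.append(ChainSpan(protein=str(protein),
                                       chain_id=str(e["chain"]),
                                       offset=int(e.get("offset", 0)),
                                       first=int(first), last=int(last)))
        return cls(spans, strict=strict)

    def to_dict(self) -> dict:
        proteins: dict[str, list] = {}
        for s in self.spans:
            proteins.setdefault(s.protein, []).append(
                {"chain": s.chain_id, "offset": s.offset,
                 "range": [s.first, s.last]})
        return {"proteins": proteins}

    @classmethod
    def from_yaml(cls, path, strict: bool = False) -> "ChainMap":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict) or "proteins" not in data:
            raise ValueError(f"{path}: expected a top-level 'proteins' mapping")
        return cls.from_dict(data, strict=strict)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def map_residue(cmap: ChainMap, protein_name: str,
                full_length_residue: int) -> list[tuple[str, int]]:
    """Functional alias for :meth:`ChainMap.map_residue`."""
    return cmap.map_residue(protein_name, full_length_residue)
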