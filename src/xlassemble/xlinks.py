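"""Chemical-crosslink restraints: parsing, FDR filtering, classification,
and Calpha-Calpha distance accounting against a coordinate model.

A BS3 crosslink between two lysines implies an upper bound on their
Calpha-Calpha distance in the assembled complex; the default satisfaction
cutoff is 30 A (11.4 A spacer plus two lysine side chains plus backbone
flexibility), inclusive at the boundary.  Links are stored in full-length
sequence numbering and translated to chain addresses via a
:class:`~xlassemble.structio.ChainMap`; a link whose protein maps to both
copies of a homodimer is resolved to the copy pair giving the shorter
distance, the standard permissive convention for copy-ambiguous CXMS data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .structio import ChainMap, StructureModel

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 30.0  # A, Calpha-Calpha for BS3
DEFAULT_FDR = 0.05

INTER = "inter_subunit"
INTRA = "intra_subunit"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class Crosslink:
    protein_a: str
    residue_a: int  # full-length numbering
    protein_b: str
    residue_b: int
    fdr: float | None = None
    spectra_count: int | None = None
    kind: str = AMBIGUOUS
    status: str = "unclassified"  # "mapped" / "unmapped" after classification

    def __post_init__(self) -> None:
        if self.residue_a < 1 or self.residue_b < 1:
            raise ValueError("residue numbers must be >= 1")
        if self.fdr is not None and not 0.0 <= self.fdr <= 1.0:
            raise ValueError("fdr must lie in [0, 1]")

    @property
    def key(self) -> tuple:
        """Unordered pair identity (direction-independent)."""
        a = (self.protein_a, self.residue_a)
        b = (self.protein_b, self.residue_b)
        return (a, b) if a <= b else (b, a)

    def __str__(self) -> str:
        return (f"{self.protein_a} K{self.residue_a} -- "
                f"{self.protein_b} K{self.residue_b}")


@dataclass
class CrosslinkSet:
    links: list[Crosslink]
    fdr_threshold: float = DEFAULT_FDR
    provenance: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for ln in self.links:
            if ln.key in seen:
                raise ValueError(f"duplicate crosslink {ln}")
            seen.add(ln.key)
            if ln.fdr is not None and ln.fdr > self.fdr_threshold:
                raise ValueError(f"link {ln} exceeds FDR threshold")

    def __len__(self) -> int:
        return len(self.links)

    def __iter__(self):
        return iter(self.links)

    def counts(self) -> dict[str, int]:
        """Per-kind/status accounting.  total = inter + intra + ambiguous."""
        out = {"total": len(self.links), INTER: 0, INTRA: 0, AMBIGUOUS: 0,
               "unmapped": 0}
        for ln in self.links:
            out[ln.kind] += 1
            if ln.status == "unmapped":
                out["unmapped"] += 1
        return out


@dataclass(frozen=True)
class LinkDistance:
    link: Crosslink
    distance: float | None  # A; None when unmappable
    satisfied: bool | None
    cutoff: float
    assignment: tuple | None = None  # ((chain, res_seq), (chain, res_seq))

    @property
    def mappable(self) -> bool:
        return self.distance is not None


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_REQUIRED = ["protein1", "residue1", "protein2", "residue2"]


def parse_crosslinks(path, fdr_threshold: float = DEFAULT_FDR) -> CrosslinkSet:
    """Read a crosslink CSV into an FDR-filtered, deduplicated set.

    Expected header: ``protein1,residue1,protein2,residue2[,fdr][,spectra]``
    ('#' lines are comments).  Rows above the FDR threshold are dropped and
    counted; A-B / B-A duplicates merge (max spectra, min fdr) keeping the
    order of first occurrence.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", skipinitialspace=True)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    for col in ("residue1", "residue2"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() | (converted != converted.round())]
        if len(bad):
            raise ValueError(
                f"{path}: non-integer residue in column {col!r}, "
                f"row {bad[0] + 2}")  # +2: header + 1-based
        df[col] = converted.astype(int)

    n_raw = len(df)
    if "fdr" in df.columns:
        keep = df["fdr"].isna() | (df["fdr"] <= fdr_threshold)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("%s: dropped %d/%d rows with fdr > %g",
                        path, dropped, n_raw, fdr_threshold)
        df = df[keep]

    merged: dict[tuple, Crosslink] = {}
    order: list[tuple] = []
    for row in df.itertuples(index=False):
        fdr = getattr(row, "fdr", None)
        fdr = None if fdr is None or pd.isna(fdr) else float(fdr)
        spectra = getattr(row, "spectra", None)
        spectra = None if spectra is None or pd.isna(spectra) else int(spectra)
        pa, ra = str(row.protein1).strip(), int(row.residue1)
        pb, rb = str(row.protein2).strip(), int(row.residue2)
        kind = INTRA if pa == pb else INTER
        ln = Crosslink(pa, ra, pb, rb, fdr=fdr, spectra_count=spectra, kind=kind)
        if ln.key in merged:
            prev = merged[ln.key]
            merged[ln.key] = replace(
                prev,
                fdr=_opt_min(prev.fdr, fdr),
                spectra_count=_opt_max(prev.spectra_count, spectra))
        else:
            merged[ln.key] = ln
            order.append(ln.key)
    links = [merged[k] for k in order]
    return CrosslinkSet(links, fdr_threshold=fdr_threshold, provenance=str(path))


def write_crosslinks(cset: CrosslinkSet, path) -> None:
    rows = []
    for ln in cset:
        rows.append({"protein1": ln.protein_a, "residue1": ln.residue_a,
                     "protein2": ln.protein_b, "residue2": ln.residue_b,
                     "fdr": ln.fdr, "spectra": ln.spectra_count})
    pd.DataFrame(rows).to_csv(path, index=False)


def _opt_min(a, b):
    vals = [v for v in (a, b) if v is not None]
    return min(vals) if vals else None


def _opt_max(a, b):
    vals = [v for v in (a, b) if v is not None]
    return max(vals) if vals else None


# ---------------------------------------------------------------------------
# Classification and distances
# ---------------------------------------------------------------------------

def classify_links(cset: CrosslinkSet, cmap: ChainMap) -> CrosslinkSet:
    """Assign inter/intra kind and mapped/unmapped status to every link.

    Links with either side outside all mapped ranges are flagged
    ``unmapped`` and counted — never silently dropped.  The conservation
    invariant holds afterwards: total = inter + intra + ambiguous.
    """
    out = []
    for ln in cset:
        kind = INTRA if ln.protein_a == ln.protein_b else INTER
        a = cmap.map_residue(ln.protein_a, ln.residue_a)
        b = cmap.map_residue(ln.protein_b, ln.residue_b)
        status = "mapped" if (a and b) else "unmapped"
        out.append(replace(ln, kind=kind, status=status))
    counts = CrosslinkSet(out, cset.fdr_threshold, cset.provenance).counts()
    logger.info("classified %d links: %d inter, %d intra, %d unmapped",
                counts["total"], counts[INTER], counts[INTRA], counts["unmapped"])
    return CrosslinkSet(out, cset.fdr_threshold, cset.provenance)


def _candidate_distance(model: StructureModel, addrs_a, addrs_b):
    """Shortest Calpha-Calpha distance over all copy assignments."""
    best = None
    for ca in addrs_a:
        pa = model.ca_coord(*ca)
        if pa is None:
            continue
        for cb in addrs_b:
            if cb == ca:
                continue  # same physical residue; not a valid assignment
            pb = model.ca_coord(*cb)
            if pb is None:
                continue
            d = float(np.linalg.norm(pa - pb))
            if best is None or d < best[0]:
                best = (d, (ca, cb))
    return best


def link_distances(model: StructureModel, cset: CrosslinkSet, cmap: ChainMap,
                   cutoff: float = DEFAULT_CUTOFF) -> list[LinkDistance]:
    """Calpha-Calpha distance and satisfaction for every mappable link.

    Homodimer copy ambiguity resolves to the shortest-distance assignment
    (logged).  A residue that maps but lacks a Calpha atom makes the link
    unmappable, with a warning.  Satisfaction is inclusive: d <= cutoff.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    out = []
    for ln in cset:
        addrs_a = cmap.map_residue(ln.protein_a, ln.residue_a)
        addrs_b = cmap.map_residue(ln.protein_b, ln.residue_b)
        if not addrs_a or not addrs_b:
            out.append(LinkDistance(ln, None, None, cutoff))
            continue
        best = _candidate_distance(model, addrs_a, addrs_b)
        if best is None:
            logger.warning("link %s maps but has no Calpha pair", ln)
            out.append(LinkDistance(ln, None, None, cutoff))
            continue
        d, assignment = best
        if len(addrs_a) > 1 or len(addrs_b) > 1:
            logger.debug("link %s: ambiguous copies resolved to %s (%.1f A)",
                         ln, assignment, d)
        out.append(LinkDistance(ln, d, d <= cutoff, cutoff,
                                assignment=assignment))
    return out


def summarize_distances(distances: list[LinkDistance]) -> dict[str, int]:
    n_sat = sum(1 for d in distances if d.satisfied)
    n_map = sum(1 for d in distances if d.mappable)
    return {"n_links": len(distances), "n_mappable": n_map,
            "n_satisfied": n_sat, "n_violated": n_map - n_sat,
            "n_unmappable": len(distances) - n_map}


def satisfaction_fraction(distances: list[LinkDistance]) -> dict:
    """Fraction of mappable links satisfied, with a per-kind breakdown."""
    n_map = sum(1 for d in distances if d.mappable)
    if n_map == 0:
        raise ValueError("no mappable links")
    by_kind: dict[str, list[int]] = {}
    for d in distances:
        if not d.mappable:
            continue
        sat, tot = by_kind.setdefault(d.link.kind, [0, 0])
        by_kind[d.link.kind] = [sat + int(d.satisfied), tot + 1]
    overall = sum(v[0] for v in by_kind.values()) / n_map
    return {"fraction": overall,
            "by_kind": {k: v[0] / v[1] for k, v in by_kind.items()},
            **summarize_distances(distances)}


def distances_table(distances: list[LinkDistance]) -> pd.DataFrame:
    """Tabular (TSV-ready) view of a link-distance report."""
    rows = []
    for d in distances:
        ln = d.link
        rows.append({
            "protein1": ln.protein_a, "residue1": ln.residue_a,
            "protein2": ln.protein_b, "residue2": ln.residue_b,
            "kind": ln.kind,
            "distance_A": None if d.distance is None else round(d.distance, 2),
            "cutoff_A": d.cutoff,
            "status": ("unmappable" if d.distance is None
                       else "satisfied" if d.satisfied else "violated"),
            "assignment": ("" if d.assignment is None else
                           f"{d.assignment[0][0]}{d.assignment[0][1]}-"
                           f"{d.assignment[1][0]}{d.assignment[1][1]}"),
        })
    return pd.DataFrame(rows)
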