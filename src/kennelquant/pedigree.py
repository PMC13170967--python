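"""Pedigree handling for quantitative-genetic evaluation.

Reads registry-style pedigree files, repairs parentage inconsistencies,
trims to phenotyped animals and their ancestors, and provides the
numerator-relationship machinery used throughout the package: inbreeding
coefficients by the Meuwissen & Luo ancestor-traversal algorithm, the
dense tabular relationship matrix A (kept as a brute-force oracle), the
sparse inverse A^-1 by Henderson's rules with inbreeding, and the sparse
Cholesky factor L with A = L L' obtained directly from the pedigree
recursion.

All matrix-producing operations require a validated, topologically
ordered pedigree (every parent precedes its offspring).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

UNKNOWN = -1  # sentinel position for an unknown parent


@dataclass
class PedigreeRecord:
    """One animal: identity, parent links and registry annotations.

    ``f`` is the coefficient of inbreeding; it is NaN until
    :func:`compute_inbreeding` has run, and 0 by definition for animals
    with both parents unknown.
    """

    id: str
    sire_id: str | None = None
    dam_id: str | None = None
    sex: str = "unknown"  # male | female | unknown
    dob: date | None = None
    colour_label: str = ""
    colour_group: str = "unknown"  # BS | NBS | unknown
    has_sbn: bool = False
    registration: str = ""
    f: float = float("nan")


@dataclass
class Correction:
    """A single repair applied by :func:`validate_and_correct`."""

    id: str
    field: str  # "sire_id" or "dam_id"
    old_value: str
    reason: str  # "self-parent" | "sex-conflict" | "chronology" | "cycle"


class Pedigree:
    """Topologically ordered collection of :class:`PedigreeRecord`.

    Provides integer position arrays ``sire_idx``/``dam_idx`` (-1 for an
    unknown parent) used by all matrix routines.
    """

    def __init__(self, records: Sequence[PedigreeRecord]):
        self.records: list[PedigreeRecord] = list(records)
        self.index: dict[str, int] = {}
        for pos, rec in enumerate(self.records):
            if rec.id in self.index:
                raise ValueError(f"duplicate animal id: {rec.id!r}")
            self.index[rec.id] = pos

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self.index

    def __getitem__(self, animal_id: str) -> PedigreeRecord:
        return self.records[self.index[animal_id]]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def _parent_positions(self) -> tuple[np.ndarray, np.ndarray]:
        n = len(self)
        sire = np.full(n, UNKNOWN, dtype=np.int64)
        dam = np.full(n, UNKNOWN, dtype=np.int64)
        for pos, rec in enumerate(self.records):
            if rec.sire_id is not None and rec.sire_id in self.index:
                sire[pos] = self.index[rec.sire_id]
            if rec.dam_id is not None and rec.dam_id in self.index:
                dam[pos] = self.index[rec.dam_id]
        return sire, dam

    @property
    def sire_idx(self) -> np.ndarray:
        return self._parent_positions()[0]

    @property
    def dam_idx(self) -> np.ndarray:
        return self._parent_positions()[1]

    def is_ordered(self) -> bool:
        """True when every known parent precedes its offspring."""
        sire, dam = self._parent_positions()
        pos = np.arange(len(self))
        ok_s = (sire == UNKNOWN) | (sire < pos)
        ok_d = (dam == UNKNOWN) | (dam < pos)
        return bool(np.all(ok_s) and np.all(ok_d))

    @property
    def inbreeding(self) -> np.ndarray:
        return np.array([r.f for r in self.records], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "sire": [r.sire_id or "" for r in self.records],
                "dam": [r.dam_id or "" for r in self.records],
                "sex": [r.sex for r in self.records],
                "dob": [r.dob.isoformat() if r.dob else "" for r in self.records],
                "colour": [r.colour_label for r in self.records],
                "colour_group": [r.colour_group for r in self.records],
                "sbn": [int(r.has_sbn) for r in self.records],
                "registration": [r.registration for r in self.records],
                "f": [r.f for r in self.records],
            }
        )


# ---------------------------------------------------------------------------
# parsing


def _parse_date(raw: str, animal_id: str) -> date | None:
    raw = (raw or "").strip()
    if not raw:
        return None
    try:
        return datetime.strptime(raw, "%Y-%m-%d").date()
    except ValueError:
        logger.warning("unreadable date %r for animal %s; set to missing", raw, animal_id)
        return None


def _norm_sex(raw: str) -> str:
    s = (raw or "").strip().lower()
    if s in {"m", "male", "dog"}:
        return "male"
    if s in {"f", "female", "bitch"}:
        return "female"
    return "unknown"


def parse_pedigree(path, colour_map: Mapping[str, str] | None = None) -> Pedigree:
    """Read a pedigree CSV into a :class:`Pedigree`.

    Expected columns: ``id, sire, dam, sex, dob, colour, sbn,
    registration`` (extra columns tolerated, empty string = missing).
    Parent ids that never appear as a row are materialized as founder
    records, with sex inferred from the parental role. Coat-colour
    labels are mapped to breed-standard (BS) / non-breed-standard (NBS)
    groups via ``colour_map``; unmapped labels become "unknown".

    Raises ``ValueError`` naming the id on duplicate rows.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "id" not in df.columns:
        raise ValueError("pedigree file must have an 'id' column")
    cmap = {str(k).strip().lower(): v for k, v in (colour_map or {}).items()}

    seen: dict[str, int] = {}
    records: list[PedigreeRecord] = []
    for _, row in df.iterrows():
        animal_id = str(row["id"]).strip()
        if not animal_id:
            raise ValueError("empty id in pedigree file")
        if animal_id in seen:
            raise ValueError(f"duplicate animal id: {animal_id!r}")
        seen[animal_id] = 1
        colour = str(row.get("colour", "") or "").strip()
        records.append(
            PedigreeRecord(
                id=animal_id,
                sire_id=str(row.get("sire", "") or "").strip() or None,
                dam_id=str(row.get("dam", "") or "").strip() or None,
                sex=_norm_sex(row.get("sex", "")),
                dob=_parse_date(row.get("dob", ""), animal_id),
                colour_label=colour,
                colour_group=cmap.get(colour.lower(), "unknown") if colour else "unknown",
                has_sbn=str(row.get("sbn", "0") or "0").strip() in {"1", "true", "yes"},
                registration=str(row.get("registration", "") or "").strip(),
            )
        )

    # materialize implicit founders for parent ids with no row of their own
    known = set(seen)
    founders: dict[str, str] = {}  # id -> inferred sex
    for rec in records:
        if rec.sire_id and rec.sire_id not in known:
            founders.setdefault(rec.sire_id, "male")
        if rec.dam_id and rec.dam_id not in known:
            founders.setdefault(rec.dam_id, "female")
    founder_records = [PedigreeRecord(id=i, sex=s) for i, s in founders.items()]
    return Pedigree(founder_records + records)


# ---------------------------------------------------------------------------
# validation / correction


def _toposort(records: list[PedigreeRecord]) -> list[PedigreeRecord] | None:
    """Kahn topological sort over parent->offspring edges; None on cycle."""
    index = {r.id: i for i, r in enumerate(records)}
    n = len(records)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=int)
    for i, r in enumerate(records):
        for pid in (r.sire_id, r.dam_id):
            if pid is not None and pid in index:
                children[index[pid]].append(i)
                indeg[i] += 1
    queue = [i for i in range(n) if indeg[i] == 0]
    out: list[int] = []
    while queue:
        nxt: list[int] = []
        for i in queue:
            out.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    nxt.append(c)
        queue = nxt
    if len(out) != n:
        return None
    return [records[i] for i in out]


def _find_cycle_edge(records: list[PedigreeRecord]) -> tuple[str, str]:
    """Return (offspring_id, parent_field) for one link closing a cycle."""
    index = {r.id: i for i, r in enumerate(records)}
    WHITE, GREY, BLACK = 0, 1, 2
    state = [WHITE] * len(records)

    def parents(i: int) -> list[tuple[int, str]]:
        r = records[i]
        out = []
        if r.sire_id in index:
            out.append((index[r.sire_id], "sire_id"))
        if r.dam_id in index:
            out.append((index[r.dam_id], "dam_id"))
        return out

    for start in range(len(records)):
        if state[start] != WHITE:
            continue
        stack: list[tuple[int, Iterable]] = [(start, iter(parents(start)))]
        state[start] = GREY
        while stack:
            node, it = stack[-1]
            advanced = False
            for p, fld in it:
                if state[p] == GREY:  # back edge: node -> p closes a cycle
                    return records[node].id, fld
                if state[p] == WHITE:
                    state[p] = GREY
                    stack.append((p, iter(parents(p))))
                    advanced = True
                    break
            if not advanced:
                state[node] = BLACK
                stack.pop()
    raise RuntimeError("no cycle found")  # pragma: no cover


def validate_and_correct(ped: Pedigree) -> tuple[Pedigree, list[Correction]]:
    """Repair parentage inconsistencies by nulling offending links.

    Rules (each fix logged with a machine-readable reason code):

    - self-parent: an animal listed as its own sire/dam;
    - sex-conflict: an id used both as a sire and as a dam somewhere in
      the file — all its parental links are nulled;
    - chronology: offspring date of birth not after a parent's date of
      birth (where both dates exist);
    - cycle: a parent link closing a directed cycle.

    Records are never deleted (phenotype linkage is preserved); the
    returned pedigree is topologically sorted and passes this function
    again with an empty log.
    """
    records = [replace(r) for r in ped.records]
    log: list[Correction] = []

    def null_link(rec: PedigreeRecord, fld: str, reason: str) -> None:
        old = getattr(rec, fld)
        if old is None:
            return
        log.append(Correction(rec.id, fld, old, reason))
        setattr(rec, fld, None)

    # self-parent
    for rec in records:
        if rec.sire_id == rec.id:
            null_link(rec, "sire_id", "self-parent")
        if rec.dam_id == rec.id:
            null_link(rec, "dam_id", "self-parent")

    # sex-conflict: same id in both parental roles
    as_sire = {r.sire_id for r in records if r.sire_id}
    as_dam = {r.dam_id for r in records if r.dam_id}
    conflicted = as_sire & as_dam
    for rec in records:
        if rec.sire_id in conflicted:
            null_link(rec, "sire_id", "sex-conflict")
        if rec.dam_id in conflicted:
            null_link(rec, "dam_id", "sex-conflict")

    # chronology: offspring must be born strictly after its parents
    index = {r.id: r for r in records}
    for rec in records:
        for fld in ("sire_id", "dam_id"):
            pid = getattr(rec, fld)
            if pid is None or pid not in index:
                continue
            parent = index[pid]
            if rec.dob is not None and parent.dob is not None and rec.dob <= parent.dob:
                null_link(rec, fld, "chronology")

    # cycles: null one closing link at a time until a topological order exists
    ordered = _toposort(records)
    while ordered is None:
        offender_id, fld = _find_cycle_edge(records)
        null_link(index[offender_id], fld, "cycle")
        ordered = _toposort(records)

    return Pedigree(ordered), log


def corrections_to_dataframe(log: list[Correction]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [c.id for c in log],
            "field": [c.field for c in log],
            "old_value": [c.old_value for c in log],
            "reason": [c.reason for c in log],
        }
    )


def trim_to_phenotyped(ped: Pedigree, ids: Iterable[str]) -> Pedigree:
    """Restrict the pedigree to ``ids`` and all their ancestors.

    Order is preserved, so a trimmed validated pedigree stays valid.
    """
    wanted = set(ids)
    unknown = wanted - set(ped.index)
    if unknown:
        raise ValueError(f"unknown ids in trim set: {sorted(unknown)[:5]}")
    keep = np.zeros(len(ped), dtype=bool)
    sire, dam = ped._parent_positions()
    for i in sorted(ped.index[a] for a in wanted):
        keep[i] = True
    # ancestors: sweep from youngest to oldest once (topological order)
    for i in range(len(ped) - 1, -1, -1):
        if keep[i]:
            if sire[i] != UNKNOWN:
                keep[sire[i]] = True
            if dam[i] != UNKNOWN:
                keep[dam[i]] = True
    return Pedigree([r for r, k in zip(ped.records, keep) if k])


# ---------------------------------------------------------------------------
# relationship machinery


def _mendelian_variances(sire: np.ndarray, dam: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Mendelian-sampling variances d_i given parent inbreeding."""
    n = len(sire)
    d = np.ones(n)
    both = (sire != UNKNOWN) & (dam != UNKNOWN)
    only_s = (sire != UNKNOWN) & (dam == UNKNOWN)
    only_d = (sire == UNKNOWN) & (dam != UNKNOWN)
    d[both] = 0.5 - 0.25 * (f[sire[both]] + f[dam[both]])
    d[only_s] = 0.75 - 0.25 * f[sire[only_s]]
    d[only_d] = 0.75 - 0.25 * f[dam[only_d]]
    return d


def compute_inbreeding(ped: Pedigree) -> Pedigree:
    """Fill inbreeding coefficients by the Meuwissen & Luo algorithm.

    For each animal with both parents known, the additive relationship
    between its parents is accumulated by walking the ancestor tree with
    gene-flow coefficients and Mendelian-sampling variances; f is half
    that relationship. Founders (and animals with a missing parent) have
    f = 0. Requires a topologically ordered pedigree.
    """
    if not ped.is_ordered():
        raise ValueError("pedigree is not topologically ordered; run validate_and_correct first")
    sire, dam = ped._parent_positions()
    n = len(ped)
    F = np.zeros(n)
    D = np.ones(n)
    c = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s != UNKNOWN and d != UNKNOWN:
            D[i] = 0.5 - 0.25 * (F[s] + F[d])
        elif s != UNKNOWN:
            D[i] = 0.75 - 0.25 * F[s]
        elif d != UNKNOWN:
            D[i] = 0.75 - 0.25 * F[d]
        if s == UNKNOWN or d == UNKNOWN:
            continue
        # diagonal of a virtual offspring of (s, d): 1 + f_i
        acc = D[i]
        c[s] += 0.5
        c[d] += 0.5
        for j in range(max(s, d), -1, -1):
            cj = c[j]
            if cj == 0.0:
                continue
            acc += cj * cj * D[j]
            js, jd = sire[j], dam[j]
            if js != UNKNOWN:
                c[js] += 0.5 * cj
            if jd != UNKNOWN:
                c[jd] += 0.5 * cj
            c[j] = 0.0
        F[i] = acc - 1.0
    out = [replace(r, f=float(F[i])) for i, r in enumerate(ped.records)]
    return Pedigree(out)


def tabular_relationship(ped: Pedigree, max_n: int = 2000) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular recursion.

    Brute-force oracle: a(j,j) = 1 + 0.5*a(sire,dam), a(i,j) =
    0.5*(a(i,sire) + a(i,dam)) for i < j, missing parents contributing 0.
    Capped at ``max_n`` animals; use the factored path beyond that.
    """
    n = len(ped)
    if n > max_n:
        raise ValueError(f"tabular A is dense; n={n} exceeds cap {max_n} — use cholesky_factor")
    if not ped.is_ordered():
        raise ValueError("pedigree is not topologically ordered")
    sire, dam = ped._parent_positions()
    A = np.zeros((n, n))
    for j in range(n):
        s, d = sire[j], dam[j]
        row = np.zeros(j)
        if s != UNKNOWN:
            row += 0.5 * A[s, :j]
        if d != UNKNOWN:
            row += 0.5 * A[d, :j]
        A[j, :j] = row
        A[:j, j] = row
        diag = 1.0
        if s != UNKNOWN and d != UNKNOWN:
            diag += 0.5 * A[s, d]
        A[j, j] = diag
    return A


def build_a_inverse(ped: Pedigree) -> sparse.csr_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding.

    Uses Mendelian-sampling variances d_i = 0.5 - 0.25(f_s + f_d)
    (adjusted for unknown parents), so the result is the exact inverse of
    the A implied by the Meuwissen-Luo inbreeding coefficients.
    Requires f already computed (NaN f is an error).
    """
    f = ped.inbreeding
    if np.any(np.isnan(f)):
        raise ValueError("inbreeding coefficients missing; run compute_inbreeding first")
    sire, dam = ped._parent_positions()
    d = _mendelian_variances(sire, dam, f)
    n = len(ped)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        alpha = 1.0 / d[i]
        add(i, i, alpha)
        parents = [p for p in (sire[i], dam[i]) if p != UNKNOWN]
        for p in parents:
            add(i, p, -0.5 * alpha)
            add(p, i, -0.5 * alpha)
        for p in parents:
            for q in parents:
                add(p, q, 0.25 * alpha)
    return sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def cholesky_factor(ped: Pedigree) -> sparse.csr_matrix:
    """Sparse lower-triangular L with A = L L'.

    Row i is 0.5*(row of sire + row of dam) plus sqrt(d_i) on the
    diagonal, where d_i is the Mendelian-sampling variance. Requires f
    computed.
    """
    f = ped.inbreeding
    if np.any(np.isnan(f)):
        raise ValueError("inbreeding coefficients missing; run compute_inbreeding first")
    sire, dam = ped._parent_positions()
    d = _mendelian_variances(sire, dam, f)
    n = len(ped)
    rows_data: list[dict[int, float]] = []
    for i in range(n):
        row: dict[int, float] = {}
        for p in (sire[i], dam[i]):
            if p != UNKNOWN:
                for j, v in rows_data[p].items():
                    row[j] = row.get(j, 0.0) + 0.5 * v
        row[i] = row.get(i, 0.0) + float(np.sqrt(d[i]))
        rows_data.append(row)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i, row in enumerate(rows_data):
        for j, v in row.items():
            rows.append(i)
            cols.append(j)
            vals.append(v)
    return sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def a_log_determinant(ped: Pedigree) -> float:
    """log|A| = sum of log Mendelian-sampling variances (A = T D T', |T| = 1)."""
    f = ped.inbreeding
    if np.any(np.isnan(f)):
        raise ValueError("inbreeding coefficients missing; run compute_inbreeding first")
    sire, dam = ped._parent_positions()
    return float(np.sum(np.log(_mendelian_variances(sire, dam, f))))


def show_breeding_score(ped: Pedigree, animal_id: str) -> int:
    """Show-breeding score SB in 0..8.

    Twice the number of parents holding a studbook number plus the
    number of grandparents holding one; unknown ancestors count as not
    holding an SBN.
    """
    if animal_id not in ped:
        raise KeyError(f"unknown animal id: {animal_id!r}")
    rec = ped[animal_id]
    score = 0
    for pid in (rec.sire_id, rec.dam_id):
        if pid is None or pid not in ped:
            continue
        parent = ped[pid]
        if parent.has_sbn:
            score += 2
        for gid in (parent.sire_id, parent.dam_id):
            if gid is not None and gid in ped and ped[gid].has_sbn:
                score += 1
    return score
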