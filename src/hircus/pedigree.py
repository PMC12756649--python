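"""Pedigree containers, file I/O, validation/repair, ordering and summary statistics.

A pedigree is a list of animal records (animal, sire, dam, sex, birth date).
Everything downstream — inbreeding, the autosomal numerator relationship
matrix A, the X-chromosomal relationship matrix S and the animal-model
design matrices — assumes a validated, topologically sorted pedigree in
which parents precede their offspring.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MALE = "M"
FEMALE = "F"

#: parent codes treated as "unknown" in input files
UNKNOWN_TOKENS = {"", "0", "NA", "na", "NaN", "nan", ".", "-", "unknown", "UNKNOWN"}


class PedigreeError(ValueError):
    """Raised for irreparable pedigree problems (cycles, conflicting duplicates)."""


@dataclass
class Pedigree:
    """Ordered collection of animal records.

    Attributes
    ----------
    df : pandas.DataFrame
        Columns ``animal`` (str), ``sire`` (str or None), ``dam`` (str or
        None), ``sex`` (``"M"``/``"F"``), ``birth_date`` (datetime64, NaT
        allowed).  Row order is meaningful.
    """

    df: pd.DataFrame
    sorted: bool = False
    validated: bool = False

    def __post_init__(self) -> None:
        self._index: dict[str, int] | None = None

    def __len__(self) -> int:
        return len(self.df)

    @property
    def animals(self) -> np.ndarray:
        return self.df["animal"].to_numpy()

    def position(self, animal_id: str) -> int:
        if self._index is None or len(self._index) != len(self.df):
            self._index = {a: i for i, a in enumerate(self.df["animal"])}
        return self._index[animal_id]

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer positions of sire and dam per animal; -1 for unknown."""
        if self._index is None or len(self._index) != len(self.df):
            self._index = {a: i for i, a in enumerate(self.df["animal"])}
        idx = self._index
        sire = np.array(
            [idx.get(s, -1) if s is not None else -1 for s in self.df["sire"]],
            dtype=np.int64,
        )
        dam = np.array(
            [idx.get(d, -1) if d is not None else -1 for d in self.df["dam"]],
            dtype=np.int64,
        )
        return sire, dam

    @property
    def sex_codes(self) -> np.ndarray:
        return self.df["sex"].to_numpy()

    def copy(self) -> "Pedigree":
        return Pedigree(self.df.copy().reset_index(drop=True), self.sorted, self.validated)


@dataclass
class IssueReport:
    """Machine-readable log of repairs applied by :func:`validate_and_repair`."""

    issues: list[dict] = field(default_factory=list)

    def add(self, animal_id: str, issue_code: str, action: str, detail: str = "") -> None:
        self.issues.append(
            {"animal_id": animal_id, "issue_code": issue_code, "action": action, "detail": detail}
        )

    def __len__(self) -> int:
        return len(self.issues)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.issues, columns=["animal_id", "issue_code", "action", "detail"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class PedigreeStats:
    n_total: int
    n_founders: int
    n_inbred: int
    n_generations: int
    mean_pedigree_depth: float
    n_sires: int
    n_dams: int
    completeness_fraction: float
    fullsib_family_count: int
    mean_fullsib_family_size: float
    F_mean_all: float
    F_mean_inbred: float
    F_min_nonzero: float
    F_max: float

    def to_series(self) -> pd.Series:
        return pd.Series(self.__dict__)


# ---------------------------------------------------------------------------
# reading


def _norm_parent(tok) -> str | None:
    if tok is None or (isinstance(tok, float) and np.isnan(tok)):
        return None
    tok = str(tok).strip()
    return None if tok in UNKNOWN_TOKENS else tok


_SEX_MAP = {
    "m": MALE, "male": MALE, "1": MALE, "s": MALE, "buck": MALE,
    "f": FEMALE, "female": FEMALE, "2": FEMALE, "d": FEMALE, "doe": FEMALE,
}


def read_pedigree(
    path,
    column_map: dict | None = None,
    date_format: str | None = None,
    sep: str | None = None,
) -> Pedigree:
    """Read a delimited pedigree file.

    Parameters
    ----------
    path : str or file-like
        Delimited text with a header row; comma or tab auto-detected when
        ``sep`` is None.
    column_map : dict, optional
        Maps canonical names (``animal``, ``sire``, ``dam``, ``sex``,
        ``birth_date``) to the file's column names.  Defaults to identity.
    date_format : str, optional
        ``strptime`` format for birth dates; default ISO-8601 parsing.
        Unparseable dates become NaT (flagged later, never fatal).
    """
    cm = {k: k for k in ("animal", "sire", "dam", "sex", "birth_date")}
    if column_map:
        cm.update(column_map)
    df = pd.read_csv(path, sep=sep, dtype=str, engine="python")
    for canon in ("animal", "sire", "dam", "sex"):
        if cm[canon] not in df.columns:
            raise PedigreeError(f"missing mandatory column {cm[canon]!r} for {canon!r}")
    out = pd.DataFrame(
        {
            "animal": df[cm["animal"]].astype(str).str.strip(),
            "sire": df[cm["sire"]].map(_norm_parent),
            "dam": df[cm["dam"]].map(_norm_parent),
            "sex": df[cm["sex"]].astype(str).str.strip().str.lower().map(_SEX_MAP),
        }
    )
    if out["sex"].isna().any():
        bad = df.loc[out["sex"].isna(), cm["sex"]].unique()
        raise PedigreeError(f"unrecognized sex codes: {list(bad)[:5]}")
    if cm["birth_date"] in df.columns:
        out["birth_date"] = pd.to_datetime(
            df[cm["birth_date"]], format=date_format, errors="coerce"
        )
    else:
        out["birth_date"] = pd.NaT
    # conflicting duplicate ids are detected here so the error can reference lines
    dup = out[out.duplicated("animal", keep=False)]
    for aid, grp in dup.groupby("animal"):
        if grp[["sire", "dam"]].astype(object).nunique(dropna=False).max() > 1:
            raise PedigreeError(
                f"duplicate animal {aid!r} with conflicting parents "
                f"(file lines {[i + 2 for i in grp.index.tolist()]})"
            )
    return Pedigree(out)


# ---------------------------------------------------------------------------
# validation / repair


def _ancestor_closure(df: pd.DataFrame) -> pd.DataFrame:
    """Insert auto-founder records for parents that have no own record."""
    known = set(df["animal"])
    extra = []
    for s in df["sire"]:
        if s is not None and s not in known:
            extra.append({"animal": s, "sire": None, "dam": None, "sex": MALE,
                          "birth_date": pd.NaT})
            known.add(s)
    for d in df["dam"]:
        if d is not None and d not in known:
            extra.append({"animal": d, "sire": None, "dam": None, "sex": FEMALE,
                          "birth_date": pd.NaT})
            known.add(d)
    if extra:
        df = pd.concat([pd.DataFrame(extra), df], ignore_index=True)
    return df


def validate_and_repair(ped: Pedigree) -> tuple[Pedigree, IssueReport]:
    """Detect and repair the classical pedigree errors.

    Repairs applied, in order: exact duplicate records collapsed; own-parent
    links severed; parents without own records inserted as founders;
    sex-inconsistent parents corrected by parent-role precedence (an animal
    used as a sire is male, as a dam female; an animal used in both roles is
    an irreparable conflict).  Remaining ancestry cycles are hard errors.
    """
    report = IssueReport()
    df = ped.df.copy().reset_index(drop=True)

    exact_dup = df.duplicated(keep="first")
    for aid in df.loc[exact_dup, "animal"]:
        report.add(aid, "duplicate_record", "collapsed", "exact duplicate removed")
    df = df[~exact_dup].reset_index(drop=True)
    if df["animal"].duplicated().any():
        bad = df.loc[df["animal"].duplicated(), "animal"].iloc[0]
        raise PedigreeError(f"conflicting duplicate records for animal {bad!r}")

    for col, code in (("sire", "own-parent"), ("dam", "own-parent")):
        self_par = df[col] == df["animal"]
        for aid in df.loc[self_par, "animal"]:
            report.add(aid, code, "parent_set_unknown", f"{col} equals own id")
        df.loc[self_par, col] = None

    df = _ancestor_closure(df)

    used_as_sire = set(df["sire"].dropna())
    used_as_dam = set(df["dam"].dropna())
    both = used_as_sire & used_as_dam
    if both:
        raise PedigreeError(f"animals used as both sire and dam: {sorted(both)[:5]}")
    sexes = df["sex"].copy()
    wrong_sire = df["animal"].isin(used_as_sire) & (sexes == FEMALE)
    wrong_dam = df["animal"].isin(used_as_dam) & (sexes == MALE)
    for aid in df.loc[wrong_sire, "animal"]:
        report.add(aid, "sex_conflict", "sex_set_male", "recorded female but used as sire")
    for aid in df.loc[wrong_dam, "animal"]:
        report.add(aid, "sex_conflict", "sex_set_female", "recorded male but used as dam")
    df.loc[wrong_sire, "sex"] = MALE
    df.loc[wrong_dam, "sex"] = FEMALE

    _detect_cycles(df)

    out = Pedigree(df.reset_index(drop=True))
    out.validated = True
    return out, report


def _detect_cycles(df: pd.DataFrame) -> None:
    """Raise naming the members of any ancestry cycle (iterative DFS)."""
    idx = {a: i for i, a in enumerate(df["animal"])}
    parents = [
        [idx[p] for p in (s, d) if p is not None]
        for s, d in zip(df["sire"], df["dam"])
    ]
    color = np.zeros(len(df), dtype=np.int8)  # 0 white, 1 gray, 2 black
    for start in range(len(df)):
        if color[start]:
            continue
        stack = [(start, iter(parents[start]))]
        color[start] = 1
        path = [start]
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                if color[p] == 1:
                    cyc = path[path.index(p):] + [p]
                    names = sorted({df["animal"].iloc[i] for i in cyc})
                    raise PedigreeError(f"ancestry cycle involving animals {names}")
                if color[p] == 0:
                    color[p] = 1
                    stack.append((p, iter(parents[p])))
                    path.append(p)
                    advanced = True
                    break
            if not advanced:
                color[node] = 2
                stack.pop()
                path.pop()


# ---------------------------------------------------------------------------
# ordering


def sort_topological(ped: Pedigree) -> Pedigree:
    """Return the pedigree reordered so every parent precedes its offspring.

    Deterministic: among animals whose parents are already placed, the one
    with the earliest birth date (unknown dates last) and then the smallest
    original row number comes first.
    """
    df = ped.df.reset_index(drop=True)
    n = len(df)
    idx = {a: i for i, a in enumerate(df["animal"])}
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i, (s, d) in enumerate(zip(df["sire"], df["dam"])):
        for p in (s, d):
            if p is not None:
                children[idx[p]].append(i)
                indeg[i] += 1
    dates = df["birth_date"]
    far_future = pd.Timestamp.max
    key = [((dates.iloc[i] if pd.notna(dates.iloc[i]) else far_future), i) for i in range(n)]
    heap = [key[i] for i in range(n) if indeg[i] == 0]
    heapq.heapify(heap)
    order = []
    while heap:
        _, i = heapq.heappop(heap)
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, key[c])
    if len(order) != n:
        raise PedigreeError("pedigree contains a cycle; run validate_and_repair first")
    out = Pedigree(df.iloc[order].reset_index(drop=True))
    out.sorted = True
    out.validated = ped.validated
    return out


def _require_sorted(ped: Pedigree) -> None:
    if not ped.sorted:
        raise PedigreeError("pedigree must be topologically sorted (sort_topological)")


# ---------------------------------------------------------------------------
# inbreeding (Meuwissen & Luo style recursion on the Cholesky of A)


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F_i = A_ii - 1 for a sorted pedigree.

    Uses the Meuwissen–Luo algorithm: for each animal the nonzero row of the
    Cholesky factor L of A is traced back through the ancestors, and
    A_ii = sum_j L_ij^2 d_j with d_j the Mendelian sampling variances.
    """
    _require_sorted(ped)
    sire, dam = ped.parent_indices()
    n = len(ped)
    F = np.zeros(n)
    d = np.zeros(n)
    for i in range(n):
        s, dm = sire[i], dam[i]
        d[i] = 0.5 - 0.25 * ((F[s] if s >= 0 else -1.0) + (F[dm] if dm >= 0 else -1.0))
        if s < 0 or dm < 0:
            F[i] = 0.0
            continue
        # walk ancestors of i from high to low index, accumulating L-row coefficients
        Aii = 0.0
        coeff = {i: 1.0}
        for j in range(i, -1, -1):
            cj = coeff.pop(j, 0.0)
            if cj == 0.0:
                continue
            Aii += cj * cj * d[j]
            sj, dj = sire[j], dam[j]
            if sj >= 0:
                coeff[sj] = coeff.get(sj, 0.0) + 0.5 * cj
            if dj >= 0:
                coeff[dj] = coeff.get(dj, 0.0) + 0.5 * cj
        F[i] = Aii - 1.0
        # F[i] computed from own row; d depends only on parents so no update needed
    return F


# ---------------------------------------------------------------------------
# statistics


def generation_numbers(ped: Pedigree) -> np.ndarray:
    """Longest-path generation number: founders 0, else 1 + max(parent gens)."""
    _require_sorted(ped)
    sire, dam = ped.parent_indices()
    gen = np.zeros(len(ped), dtype=np.int64)
    for i in range(len(ped)):
        g = -1
        if sire[i] >= 0:
            g = max(g, gen[sire[i]])
        if dam[i] >= 0:
            g = max(g, gen[dam[i]])
        gen[i] = g + 1
    return gen


def pedigree_depths(ped: Pedigree) -> np.ndarray:
    """Complete-generation-equivalent depth per animal.

    Depth_i = sum over known ancestors of (1/2)^g where g is the generation
    distance (parents g=1).  Computed by the recursion
    depth_i = 0.5 * (1 + depth_sire) + 0.5 * (1 + depth_dam), unknown
    parents contributing 0.
    """
    _require_sorted(ped)
    sire, dam = ped.parent_indices()
    depth = np.zeros(len(ped))
    for i in range(len(ped)):
        t = 0.0
        if sire[i] >= 0:
            t += 0.5 * (1.0 + depth[sire[i]])
        if dam[i] >= 0:
            t += 0.5 * (1.0 + depth[dam[i]])
        depth[i] = t
    return depth


def pedigree_statistics(ped: Pedigree, F: np.ndarray | None = None) -> PedigreeStats:
    """Summary statistics of a validated, sorted pedigree."""
    _require_sorted(ped)
    if F is None:
        F = inbreeding(ped)
    df = ped.df
    sire, dam = ped.parent_indices()
    both_known = (sire >= 0) & (dam >= 0)
    founders = (sire < 0) & (dam < 0)
    gen = generation_numbers(ped)
    depth = pedigree_depths(ped)
    fam = pd.DataFrame({"s": sire[both_known], "d": dam[both_known]})
    sizes = fam.groupby(["s", "d"]).size()
    fullsib = sizes[sizes >= 2]
    inbred = F > 1e-12
    nonzeroF = F[inbred]
    return PedigreeStats(
        n_total=len(df),
        n_founders=int(founders.sum()),
        n_inbred=int(inbred.sum()),
        n_generations=int(gen.max()) + 1,
        mean_pedigree_depth=float(depth.mean()),
        n_sires=int(pd.unique(sire[sire >= 0]).size),
        n_dams=int(pd.unique(dam[dam >= 0]).size),
        completeness_fraction=float(both_known.mean()),
        fullsib_family_count=int(len(fullsib)),
        mean_fullsib_family_size=float(fullsib.mean()) if len(fullsib) else 0.0,
        F_mean_all=float(F.mean()),
        F_mean_inbred=float(nonzeroF.mean()) if len(nonzeroF) else 0.0,
        F_min_nonzero=float(nonzeroF.min()) if len(nonzeroF) else 0.0,
        F_max=float(F.max()),
    )
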