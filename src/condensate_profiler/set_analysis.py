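"""Set overlaps, hypergeometric enrichment and the s0-moderated t-test.

Protein and mRNA lists from the granule assignments are compared by exact
set arithmetic (Euler-diagram counts), tested for over-representation in
user-supplied custom gene sets by the upper-tail hypergeometric test with
Benjamini-Hochberg correction, and — as the classical IP-enrichment
baseline — screened by a two-sample Welch t-test moderated by a constant
``s0`` added to the standard error, with a label-permutation FDR.

Identifiers are normalized before comparison: whitespace trimmed, case
folded, and the yeast protein-name "p" suffix dropped (Dcp1p == Dcp1),
since published lists mix both forms.
"""

from __future__ import annotations

import itertools
import logging
import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def normalize_id(identifier: str) -> str:
    s = identifier.strip()
    s = re.sub(r"(?<=\d)p$", "", s, flags=re.IGNORECASE)
    return s.casefold()


@dataclass
class GeneSet:
    """A named, de-duplicated, case-normalized identifier set."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set needs a non-empty name")
        self.members = frozenset(self.members)

    @classmethod
    def from_ids(cls, name: str, ids: Iterable[str]) -> "GeneSet":
        return cls(name=name, members=frozenset(normalize_id(i) for i in ids if i.strip()))

    def __len__(self) -> int:
        return len(self.members)

    def __and__(self, other: "GeneSet") -> frozenset[str]:
        return self.members & other.members


def read_gene_list(path, name: str | None = None) -> GeneSet:
    """One identifier per line; blank lines and '#' comments skipped."""
    with open(str(path)) as fh:
        ids = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    return GeneSet.from_ids(name or str(path), ids)


def read_gmt(path) -> list[GeneSet]:
    """GMT-like TSV: name <TAB> description <TAB> member..."""
    out = []
    with open(str(path)) as fh:
        for ln in fh:
            parts = ln.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            out.append(GeneSet.from_ids(parts[0], parts[2:]))
    return out


@dataclass
class OverlapResult:
    """Exact Euler-diagram regions for two identifier sets."""

    name_a: str
    name_b: str
    only_a: tuple[str, ...]
    only_b: tuple[str, ...]
    both: tuple[str, ...]

    @property
    def n_a(self) -> int:
        return len(self.only_a) + len(self.both)

    @property
    def n_b(self) -> int:
        return len(self.only_b) + len(self.both)

    @property
    def n_intersection(self) -> int:
        return len(self.both)

    def to_dict(self) -> dict:
        return {
            "A": self.name_a,
            "B": self.name_b,
            "|A|": self.n_a,
            "|B|": self.n_b,
            "|A&B|": self.n_intersection,
            "|A-B|": len(self.only_a),
            "|B-A|": len(self.only_b),
        }


def set_overlap(a: GeneSet, b: GeneSet) -> OverlapResult:
    if not a.members or not b.members:
        raise ValueError("both sets must be non-empty")
    return OverlapResult(
        name_a=a.name,
        name_b=b.name,
        only_a=tuple(sorted(a.members - b.members)),
        only_b=tuple(sorted(b.members - a.members)),
        both=tuple(sorted(a.members & b.members)),
    )


@dataclass
class EnrichmentResult:
    term: str
    overlap: int  # k
    term_size: int  # K (within universe)
    query_size: int  # n (within universe)
    universe_size: int  # N
    p_value: float
    p_adjusted: float
    direction: str  # enriched / depleted

    @property
    def expected(self) -> float:
        return self.query_size * self.term_size / self.universe_size


def hypergeom_enrich(
    query: GeneSet,
    terms: Sequence[GeneSet],
    universe: GeneSet,
    direction: str = "enriched",
) -> list[EnrichmentResult]:
    """Hypergeometric over- (or under-) representation of ``query`` in each
    term, with BH adjustment across terms.

    Query and term members outside the universe are dropped (logged).
    The upper-tail p is P(X >= k); depletion uses the lower tail
    P(X <= k).
    """
    if direction not in ("enriched", "depleted"):
        raise ValueError("direction must be 'enriched' or 'depleted'")
    if not universe.members:
        raise ValueError("empty universe")
    uni = universe.members
    q = query.members & uni
    dropped = len(query.members) - len(q)
    if dropped:
        logger.info("%d query ids outside the universe dropped", dropped)

    raw: list[tuple[str, int, int]] = []
    for term in terms:
        t = term.members & uni
        if not t:
            raise ValueError(f"term {term.name!r} has no members in the universe")
        raw.append((term.name, len(q & t), len(t)))

    n_uni, n_query = len(uni), len(q)
    pvals = []
    for _, k, big_k in raw:
        if direction == "enriched":
            p = stats.hypergeom.sf(k - 1, n_uni, big_k, n_query)
        else:
            p = stats.hypergeom.cdf(k, n_uni, big_k, n_query)
        pvals.append(min(float(p), 1.0))
    adjusted = multipletests(pvals, method="fdr_bh")[1] if pvals else []
    return [
        EnrichmentResult(
            term=name,
            overlap=k,
            term_size=big_k,
            query_size=n_query,
            universe_size=n_uni,
            p_value=p,
            p_adjusted=float(adj),
            direction=direction,
        )
        for (name, k, big_k), p, adj in zip(raw, pvals, adjusted)
    ]


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (statsmodels-backed)."""
    return multipletests(list(pvals), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# s0-moderated t-test with permutation FDR


@dataclass
class DiffStatResult:
    """Per-feature s0-moderated t statistics with permutation q-values."""

    table: pd.DataFrame  # columns: mean_a, mean_b, t_mod, q_value
    s0: float
    n_perm: int
    seed: int

    def significant(self, fdr: float = 0.01) -> pd.Index:
        return self.table.index[self.table["q_value"] < fdr]


def _moderated_t(a: np.ndarray, b: np.ndarray, s0: float) -> np.ndarray:
    """t' = (mean_a - mean_b) / (se_welch + s0), row-wise."""
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    se = np.sqrt(var_a / a.shape[1] + var_b / b.shape[1])
    return (mean_a - mean_b) / (se + s0)


def s0_ttest(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    s0: float = 2.0,
    n_perm: int = 250,
    seed: int = 0,
) -> DiffStatResult:
    """Two-sample moderated t-test between replicate groups A and B.

    The statistic is the Welch t with ``s0`` added to the standard error,
    damping the significance of small absolute differences. q-values come
    from a group-label permutation null: all distinct relabelings when
    their number is at most ``n_perm``, otherwise ``n_perm`` seeded draws;
    the q-value of a feature is the Storey-style ratio of mean null
    exceedances to observed exceedances of |t'|, clipped to [0, 1] and
    monotonized in |t'|.
    """
    if not matrix_a.index.equals(matrix_b.index):
        raise ValueError("feature indices of the two groups differ")
    na, nb = matrix_a.shape[1], matrix_b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 replicates per group")
    a = matrix_a.to_numpy(dtype=float)
    b = matrix_b.to_numpy(dtype=float)
    t_obs = _moderated_t(a, b, s0)

    pooled = np.concatenate([a, b], axis=1)
    all_combos = math.comb(na + nb, na)
    rng = np.random.default_rng(seed)
    if all_combos <= n_perm:
        combos = list(itertools.combinations(range(na + nb), na))
    else:
        combos = []
        for _ in range(n_perm):
            idx = rng.permutation(na + nb)[:na]
            combos.append(tuple(sorted(idx)))

    abs_obs = np.abs(t_obs)
    order = np.argsort(-abs_obs, kind="stable")
    sorted_abs = abs_obs[order]
    # observed exceedances: rank within the sorted |t'| list
    obs_exceed = np.arange(1, abs_obs.size + 1)

    null_exceed = np.zeros(abs_obs.size)
    cols = np.arange(na + nb)
    for combo in combos:
        in_a = np.zeros(na + nb, dtype=bool)
        in_a[list(combo)] = True
        t_null = _moderated_t(pooled[:, cols[in_a]], pooled[:, cols[~in_a]], s0)
        # for each observed threshold, count null |t| >= threshold
        null_sorted = np.sort(np.abs(t_null))
        null_exceed += abs_obs.size - np.searchsorted(null_sorted, sorted_abs, side="left")
    mean_null = null_exceed / len(combos)

    q_sorted = np.minimum(1.0, mean_null / obs_exceed)
    q_sorted = np.maximum.accumulate(q_sorted)  # monotone non-increasing in |t'|
    q = np.empty_like(q_sorted)
    q[order] = q_sorted

    table = pd.DataFrame(
        {
            "mean_a": a.mean(axis=1),
            "mean_b": b.mean(axis=1),
            "t_mod": t_obs,
            "q_value": q,
        },
        index=matrix_a.index,
    )
    return DiffStatResult(table=table, s0=s0, n_perm=len(combos), seed=seed)
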