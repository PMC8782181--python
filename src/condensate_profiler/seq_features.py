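"""RNA and protein sequence features of granule-associated gene sets.

Covers the transcript-level comparisons made between condensate-enriched
RNA pools and the whole-transcriptome background: length decomposition
into 5'UTR/CDS/3'UTR, adenosine and AU content, polyA tracts (maximal
runs of >= 8 adenosines), translational efficiency from ribosome
footprint vs. total counts, median-of-ratios count normalization,
Mann-Whitney group comparisons, and amino-acid composition profiling of
protein sets against a background proteome.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_BASES = set("ACGTUN")


@dataclass
class TranscriptRecord:
    """A transcript sequence with its UTR/CDS length decomposition."""

    id: str
    sequence: str
    utr5_len: int
    cds_len: int
    utr3_len: int

    def __post_init__(self) -> None:
        if min(self.utr5_len, self.cds_len, self.utr3_len) < 0:
            raise ValueError("region lengths must be non-negative")
        if self.sequence and len(self.sequence) != self.total_len:
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != "
                f"utr5+cds+utr3 = {self.total_len}"
            )

    @property
    def total_len(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len

    @property
    def cds(self) -> str:
        return self.sequence[self.utr5_len : self.utr5_len + self.cds_len]


def _clean_seq(seq: str) -> str:
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGTN")
    if bad:
        raise ValueError(f"illegal characters in sequence: {sorted(bad)}")
    return s


def polya_tracts(seq: str, min_run: int = 8) -> list[tuple[int, int]]:
    """Maximal runs of adenosine of length >= ``min_run``.

    Returns 0-based half-open (start, end) intervals. Case-insensitive;
    U is treated as T (so never as A).
    """
    s = _clean_seq(seq)
    return [
        m.span()
        for m in re.finditer(rf"A{{{min_run},}}", s)
    ]


def base_content(seq: str, bases: Iterable[str]) -> float:
    """Fraction of positions whose base is in ``bases`` (U === T)."""
    s = _clean_seq(seq)
    wanted = {b.upper().replace("U", "T") for b in bases}
    return sum(s.count(b) for b in wanted) / len(s)


def select_utrs(candidates: pd.DataFrame) -> pd.DataFrame:
    """Pick one UTR per (transcript, side) by highest read support.

    ``candidates`` columns: id, side (5 or 3), length, read_support.
    Ties break to the longest candidate, then first in input order.
    """
    required = {"id", "side", "length", "read_support"}
    missing = required - set(candidates.columns)
    if missing:
        raise ValueError(f"candidate table missing columns {sorted(missing)}")
    df = candidates.reset_index(drop=True)
    df["_order"] = np.arange(len(df))
    df = df.sort_values(
        ["id", "side", "read_support", "length", "_order"],
        ascending=[True, True, False, False, True],
    )
    tied = df.duplicated(subset=["id", "side", "read_support"], keep=False)
    if tied.any():
        logger.info(
            "read-support ties for %d (id, side) groups; longest candidate kept",
            int(df[tied].groupby(["id", "side"]).ngroups),
        )
    out = df.groupby(["id", "side"], sort=True).head(1)
    return out.drop(columns="_order").reset_index(drop=True)


SIGNIFICANCE_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_code(p: float) -> str:
    for cut, code in SIGNIFICANCE_LEVELS:
        if p < cut:
            return code
    return "ns"


@dataclass
class GroupComparison:
    """Mann-Whitney comparison of a feature between a set and background."""

    group: str
    n_sample: int
    n_background: int
    u_statistic: float
    p_value: float
    median_difference: float
    significance: str
    method: Literal["exact", "asymptotic"]


def mannwhitney_compare(
    sample: Sequence[float],
    background: Sequence[float],
    group: str = "sample",
    exact_max: int = 20,
) -> GroupComparison:
    """Two-sided Mann-Whitney U test of ``sample`` against ``background``.

    Exact null distribution (full enumeration) when the smaller group has
    at most ``exact_max`` observations and there are no ties; otherwise
    the normal approximation with tie and continuity correction.
    """
    x = np.asarray(sample, dtype=float)
    y = np.asarray(background, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both inputs must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= exact_max and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    p = float(min(res.pvalue, 1.0))
    return GroupComparison(
        group=group,
        n_sample=int(x.size),
        n_background=int(y.size),
        u_statistic=float(res.statistic),
        p_value=p,
        median_difference=float(np.median(x) - np.median(y)),
        significance=significance_code(p),
        method=method,
    )


# ---------------------------------------------------------------------------
# Counts: normalization, IP enrichment, translational efficiency


@dataclass
class CountMatrix:
    """Gene x library integer counts with per-library class labels."""

    counts: pd.DataFrame
    library_class: pd.Series  # library -> {"IP", "total", "footprint"}

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        self.library_class = self.library_class.reindex(self.counts.columns)
        if self.library_class.isna().any():
            raise ValueError("every library needs a class label")

    def libraries(self, cls: str) -> list[str]:
        return list(self.library_class.index[self.library_class == cls])

    def write_tsv(self, path) -> None:
        out = self.counts.copy()
        out.columns = [
            f"{c}|{self.library_class[c]}" for c in out.columns
        ]
        out.index.name = "gene"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene")
        names, classes = zip(*(c.rsplit("|", 1) for c in df.columns))
        df.columns = list(names)
        return cls(df, pd.Series(classes, index=list(names)))


def normalize_counts(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios size factors (one per library).

    For each gene with non-zero counts in every library, the ratio of its
    count to its geometric mean across libraries is formed; a library's
    size factor is the median of these ratios.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if df.shape[1] < 2:
        raise ValueError("need at least two libraries")
    mat = df.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no gene has non-zero counts in every library")
    log_mat = np.log(mat[all_nonzero])
    log_gm = log_mat.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_mat - log_gm, axis=0))
    return pd.Series(factors, index=df.columns, name="size_factor")


def _normalized_means(
    cm: CountMatrix, numerator: str, denominator: str
) -> tuple[pd.Series, pd.Series]:
    num_libs, den_libs = cm.libraries(numerator), cm.libraries(denominator)
    if not num_libs or not den_libs:
        raise ValueError(f"need {numerator} and {denominator} libraries")
    sf = normalize_counts(cm.counts)
    normed = cm.counts / sf
    return normed[num_libs].mean(axis=1), normed[den_libs].mean(axis=1)


def log2_enrichment(cm: CountMatrix, pseudocount: float = 0.5) -> pd.Series:
    """Per-gene log2 enrichment of the IP libraries over matched totals."""
    ip, total = _normalized_means(cm, "IP", "total")
    return np.log2((ip + pseudocount) / (total + pseudocount)).rename("log2_enrichment")


def translational_efficiency(
    footprints: pd.DataFrame,
    totals: pd.DataFrame,
    pseudocount: float = 0.5,
) -> pd.Series:
    """TE = log2 of ribosome-footprint over matched total-RNA abundance.

    Inputs are size-factor-normalized count tables (see
    :func:`normalize_counts`); replicate columns are averaged before the
    ratio is taken.
    """
    if not footprints.index.equals(totals.index):
        if set(footprints.index) != set(totals.index):
            raise ValueError("footprint and total tables cover different genes")
        totals = totals.reindex(footprints.index)
    fp = footprints.mean(axis=1)
    tot = totals.mean(axis=1)
    return np.log2((fp + pseudocount) / (tot + pseudocount)).rename("TE")


def delta_te(te_stress: pd.Series, te_unstressed: pd.Series) -> pd.Series:
    """Per-gene TE change under stress (stress minus unstressed)."""
    common = te_stress.index.intersection(te_unstressed.index)
    return (te_stress[common] - te_unstressed[common]).rename("delta_TE")


# ---------------------------------------------------------------------------
# Transcript feature table


def transcript_features(
    records: Iterable[TranscriptRecord],
    min_run: int = 8,
    region: Literal["transcript", "cds"] = "transcript",
) -> pd.DataFrame:
    """Per-transcript feature table: lengths, A and AU content, polyA tracts.

    ``region`` selects whether composition and tract scanning use the
    whole transcript or the CDS only.
    """
    rows = []
    for rec in records:
        seq = rec.sequence if region == "transcript" else rec.cds
        rows.append(
            {
                "id": rec.id,
                "total_len": rec.total_len,
                "utr5_len": rec.utr5_len,
                "cds_len": rec.cds_len,
                "utr3_len": rec.utr3_len,
                "a_content": base_content(seq, "A") if seq else np.nan,
                "au_content": base_content(seq, "AT") if seq else np.nan,
                "polya_tracts": len(polya_tracts(seq, min_run)) if seq else 0,
            }
        )
    return pd.DataFrame(rows).set_index("id")


def compare_feature(
    features: pd.DataFrame,
    column: str,
    sample_ids: Iterable[str],
    group: str = "sample",
    background_ids: Iterable[str] | None = None,
) -> GroupComparison:
    """Mann-Whitney comparison of one feature column for a gene set
    against the background (all rows by default)."""
    ids = [i for i in sample_ids if i in features.index]
    bg = features.index if background_ids is None else list(background_ids)
    return mannwhitney_compare(
        features.loc[ids, column].dropna(),
        features.loc[bg, column].dropna(),
        group=group,
    )


# ---------------------------------------------------------------------------
# Amino-acid composition profiling


def _composition(seqs: Sequence[str], alphabet: list[str]) -> np.ndarray:
    counts = np.zeros(len(alphabet))
    index = {a: i for i, a in enumerate(alphabet)}
    for s in seqs:
        for ch in s.upper():
            if ch in index:
                counts[index[ch]] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no countable symbols in sequence collection")
    return counts / total


def composition_profile(
    sample_seqs: Sequence[str],
    background_seqs: Sequence[str],
    groups: dict[str, str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Relative composition enrichment of a sequence set over a background.

    For each residue (and each named residue group, e.g. aromatic = FWY)
    the statistic is (C_sample - C_background) / C_background on pooled
    composition. Two-sided p-values come from bootstrap resampling of
    whole sequences within each collection.
    """
    if not sample_seqs or not background_seqs:
        raise ValueError("sequence collections must be non-empty")
    alphabet = sorted({ch for s in list(sample_seqs) + list(background_seqs) for ch in s.upper()})
    groups = groups or {}

    def group_matrix(comp: np.ndarray) -> np.ndarray:
        sym = comp
        grp = np.array(
            [sum(comp[alphabet.index(a)] for a in members if a in alphabet)
             for members in groups.values()]
        )
        return np.concatenate([sym, grp])

    c_s = group_matrix(_composition(sample_seqs, alphabet))
    c_b = group_matrix(_composition(background_seqs, alphabet))
    zero_bg = c_b == 0
    if zero_bg.any():
        names_all = alphabet + list(groups)
        bad = [n for n, z in zip(names_all, zero_bg) if z]
        raise ValueError(f"background composition is zero for {bad}")
    observed = (c_s - c_b) / c_b

    # per-sequence count matrices make each bootstrap replicate a sum
    def seq_counts(seqs: Sequence[str]) -> np.ndarray:
        mat = np.zeros((len(seqs), len(alphabet)))
        for i, s in enumerate(seqs):
            for ch in s.upper():
                j = alphabet.index(ch)
                mat[i, j] += 1
        return mat

    cnt_s, cnt_b = seq_counts(sample_seqs), seq_counts(background_seqs)
    rng = np.random.default_rng(seed)
    n_stats = observed.size
    boots = np.empty((n_boot, n_stats))
    for b in range(n_boot):
        i_s = rng.integers(0, len(sample_seqs), len(sample_seqs))
        i_b = rng.integers(0, len(background_seqs), len(background_seqs))
        cs = cnt_s[i_s].sum(axis=0)
        cb = cnt_b[i_b].sum(axis=0)
        cs = cs / cs.sum()
        cb = cb / cb.sum()
        gs, gb = group_matrix(cs), group_matrix(cb)
        with np.errstate(divide="ignore", invalid="ignore"):
            boots[b] = np.where(gb > 0, (gs - gb) / np.where(gb > 0, gb, 1.0), np.inf)

    le = (boots <= 0).sum(axis=0)
    ge = (boots >= 0).sum(axis=0)
    p = np.minimum(1.0, 2.0 * (np.minimum(le, ge) + 1) / (n_boot + 1))
    names = alphabet + list(groups)
    kind = ["residue"] * len(alphabet) + ["group"] * len(groups)
    return pd.DataFrame(
        {"kind": kind, "enrichment": observed, "p_value": p},
        index=pd.Index(names, name="symbol"),
    )


def load_aa_groups(path=None) -> dict[str, str]:
    """Named amino-acid property groups (editable TSV: name<TAB>residues)."""
    if path is None:
        from importlib.resources import files

        path = files("condensate_profiler.data").joinpath("aa_groups.tsv")
    out: dict[str, str] = {}
    with open(str(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, members = line.split("\t")
            out[name] = members
    return out
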