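"""Ingestion of quantitative proteomics tables into clustering-ready profiles.

The processing chain mirrors a LOPIT-style fractionation analysis:

    read -> flag filter -> elution-detection filter -> tagged-IP filter
         -> impute -> (rollup) -> replicate average -> sum normalize
         -> split by condition -> per-row standardize

Zeros in input tables encode non-detection and are converted to missing on
read. Missingness in label-free MS is left-censored (low-abundance values
fall below detection), so the default imputation is QRILC — quantile
regression imputation of left-censored data — with a Perseus-style
down-shifted-normal alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .design import (
    SampleKey,
    StudyDesign,
    format_generic_column,
    parse_generic_column,
)

logger = logging.getLogger(__name__)

COLUMN_LEVELS = ("bait", "condition", "fraction", "replicate")

MAXQUANT_FLAG_COLUMNS = ("Reverse", "Potential contaminant", "Only identified by site")


def _columns_index(keys: list[SampleKey]) -> pd.MultiIndex:
    return pd.MultiIndex.from_tuples(
        [(k.bait, k.condition, k.fraction, k.replicate) for k in keys],
        names=COLUMN_LEVELS,
    )


@dataclass
class QuantTable:
    """Feature x sample intensity matrix keyed by the study design.

    ``data`` holds one row per feature (peptide or protein) and one column
    per (bait, condition, fraction, replicate); missing values are NaN.
    Intensities are linear unless ``log2_scale`` is set.
    """

    data: pd.DataFrame
    level: Literal["peptide", "protein"] = "protein"
    protein_map: pd.Series | None = None  # peptide id -> protein id
    log2_scale: bool = False
    replicate_averaged: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if self.level == "peptide" and self.protein_map is None:
            raise ValueError("peptide-level table requires a peptide->protein map")
        with np.errstate(invalid="ignore"):
            if not self.log2_scale and (self.data.to_numpy() < 0).any():
                raise ValueError("negative intensities in linear-scale table")

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "QuantTable":
        return replace(
            self,
            data=self.data.copy(),
            protein_map=None if self.protein_map is None else self.protein_map.copy(),
        )

    def to_log2(self) -> "QuantTable":
        if self.log2_scale:
            return self
        return replace(self, data=np.log2(self.data), log2_scale=True)

    def to_linear(self) -> "QuantTable":
        if not self.log2_scale:
            return self
        return replace(self, data=np.exp2(self.data), log2_scale=False)

    def write_tsv(self, path) -> None:
        out = self.data.copy()
        out.columns = [
            format_generic_column(SampleKey(*c)) for c in self.data.columns
        ]
        out = out.fillna(0.0)  # zero encodes "not detected"
        out.index.name = "id"
        out.to_csv(path, sep="\t")


@dataclass
class ProfileMatrix:
    """Per-condition concatenated profile vectors (proteins x columns)."""

    values: pd.DataFrame  # columns: MultiIndex (bait, condition, fraction)
    condition: str
    sum_normalized: bool = False
    standardized: bool = False

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def dimensionality(self) -> int:
        return self.values.shape[1]

    def write_tsv(self, path) -> None:
        out = self.values.copy()
        out.columns = ["|".join(map(str, c)) for c in out.columns]
        out.index.name = "id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, condition: str) -> "ProfileMatrix":
        df = pd.read_csv(path, sep="\t", index_col="id")
        df.columns = pd.MultiIndex.from_tuples(
            [tuple(c.split("|")) for c in df.columns],
            names=("bait", "condition", "fraction"),
        )
        return cls(values=df, condition=condition, sum_normalized=True, standardized=True)


# ---------------------------------------------------------------------------
# Readers


def read_quant_table(
    path,
    dialect: Literal["generic_tsv", "maxquant_peptides", "maxquant_proteingroups"],
    design: StudyDesign,
    column_map: dict[str, str] | None = None,
) -> QuantTable:
    """Read a quantification table; zeros become missing, flagged rows drop.

    ``column_map`` translates MaxQuant sample names (the suffix of
    ``LFQ intensity <sample>`` / ``Intensity <sample>`` columns) to
    generic ``bait|condition|fraction|repK`` keys; it is required for the
    MaxQuant dialects.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if dialect == "generic_tsv":
        return _from_generic(df, design)
    if dialect in ("maxquant_peptides", "maxquant_proteingroups"):
        if column_map is None:
            raise ValueError(f"dialect {dialect!r} requires a column_map")
        return _from_maxquant(df, design, dialect, column_map)
    raise ValueError(f"unknown dialect {dialect!r}")


def _numeric(df: pd.DataFrame) -> pd.DataFrame:
    try:
        vals = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"malformed numeric cell in quant table: {exc}") from exc
    return vals.mask(vals == 0.0)  # zero = not detected


def _from_generic(df: pd.DataFrame, design: StudyDesign) -> QuantTable:
    if "id" not in df.columns:
        raise ValueError("generic dialect requires an 'id' column")
    df = df.set_index("id")
    keys = [parse_generic_column(c) for c in df.columns]
    known = {
        (s.bait, s.condition) for s in design.sample_sets
    }
    for k in keys:
        if (k.bait, k.condition) not in known or k.fraction not in design.fractions:
            raise ValueError(f"intensity column {k} not in design")
    vals = _numeric(df)
    vals.columns = _columns_index(keys)
    return QuantTable(data=vals, level="protein")


def _from_maxquant(
    df: pd.DataFrame,
    design: StudyDesign,
    dialect: str,
    column_map: dict[str, str],
) -> QuantTable:
    n0 = len(df)
    for flag in MAXQUANT_FLAG_COLUMNS:
        if flag in df.columns:
            df = df[df[flag].fillna("") != "+"]
    if len(df) < n0:
        logger.info("flag filter removed %d of %d rows", n0 - len(df), n0)

    if dialect == "maxquant_proteingroups":
        id_col, prefix = "Majority protein IDs", "LFQ intensity "
        ids = df[id_col].str.split(";").str[0]
        protein_map = None
        level = "protein"
    else:
        id_col, prefix = "Sequence", "Intensity "
        ids = df[id_col]
        proteins = df["Proteins"].str.split(";").str[0]  # first mapped protein wins
        protein_map = pd.Series(proteins.to_numpy(), index=ids.to_numpy())
        if protein_map.isna().any():
            bad = protein_map.index[protein_map.isna()].tolist()
            raise ValueError(f"peptides mapped to no protein: {bad[:5]}")
        level = "peptide"

    sample_cols = [c for c in df.columns if c.startswith(prefix)]
    keys = []
    for c in sample_cols:
        sample = c[len(prefix):]
        if sample not in column_map:
            raise ValueError(f"intensity column {c!r} has no design mapping")
        keys.append(parse_generic_column(column_map[sample]))
    vals = _numeric(df[sample_cols].set_axis(ids.to_numpy(), axis=0))
    vals.columns = _columns_index(keys)
    return QuantTable(data=vals, level=level, protein_map=protein_map)


# ---------------------------------------------------------------------------
# Filters


def elution_filter(q: QuantTable, design: StudyDesign) -> QuantTable:
    """Discard features lacking any non-zero measurement in any elution
    (IP) fraction, tagged or untagged."""
    ip = design.fractions[0]
    cols = q.data.columns.get_level_values("fraction") == ip
    if not cols.any():
        raise ValueError("design has no elution (IP) columns")
    keep = q.data.loc[:, cols].notna().any(axis=1)
    return replace(q, data=q.data.loc[keep])


def ip_filter(q: QuantTable, design: StudyDesign) -> QuantTable:
    """Keep only features detected in at least one *tagged* IP elution
    column (any condition) — the IP-centric selection."""
    ip = design.fractions[0]
    tagged = {(s.bait, s.condition) for s in design.sample_sets if s.tagged}
    mask = np.array(
        [
            (c[0], c[1]) in tagged and c[2] == ip
            for c in q.data.columns
        ]
    )
    if not mask.any():
        raise ValueError("design has no tagged IP columns")
    keep = q.data.loc[:, mask].notna().any(axis=1)
    return replace(q, data=q.data.loc[keep])


# ---------------------------------------------------------------------------
# Imputation

MIN_OBSERVED_FOR_IMPUTATION = 5


def _check_imputable(data: pd.DataFrame) -> None:
    n_obs = data.notna().sum(axis=0)
    bad = n_obs[n_obs < MIN_OBSERVED_FOR_IMPUTATION]
    if len(bad):
        raise ValueError(
            "columns with fewer than "
            f"{MIN_OBSERVED_FOR_IMPUTATION} observed values: {list(bad.index)[:5]}"
        )


def impute_qrilc(
    q: QuantTable, seed: int, quantile_cut: float = 0.01
) -> QuantTable:
    """Quantile-regression imputation of left-censored data.

    Per column, the mean and sd of the underlying complete normal are
    estimated by regressing the sorted observed log-intensities on the
    standard-normal quantiles of their plotting positions *within the full
    column* (the lowest ranks are taken by the censored cells). Missing
    cells are then drawn from that normal truncated above at its
    (missing-fraction + ``quantile_cut``) quantile, i.e. inside the
    censored left tail. Observed cells are never altered.
    """
    was_linear = not q.log2_scale
    work = q.to_log2()
    data = work.data.copy()
    if not data.isna().any().any():
        return q
    _check_imputable(data)
    rng = np.random.default_rng(seed)
    for j, col in enumerate(data.columns):
        x = data[col].to_numpy(copy=True)
        miss = np.isnan(x)
        if not miss.any():
            continue
        n, n_miss = x.size, int(miss.sum())
        obs_sorted = np.sort(x[~miss])
        # Blom plotting positions over the full column: observed values
        # occupy overall ranks n_miss+1 .. n.
        ranks = np.arange(n_miss + 1, n + 1)
        p = (ranks - 0.375) / (n + 0.25)
        z = stats.norm.ppf(p)
        slope, intercept = np.polyfit(z, obs_sorted, 1)
        mu, sigma = float(intercept), float(abs(slope))
        if sigma == 0.0:
            x[miss] = mu
            data[col] = x
            continue
        q_trunc = min(n_miss / n + quantile_cut, 1.0 - 1e-9)
        upper = mu + sigma * stats.norm.ppf(q_trunc)
        a = (upper - mu) / sigma  # truncnorm upper bound in standard units
        draws = stats.truncnorm.rvs(
            -np.inf, a, loc=mu, scale=sigma, size=n_miss, random_state=rng
        )
        x[miss] = draws
        data[col] = x
    out = replace(work, data=data)
    return out.to_linear() if was_linear else out


def impute_downshift(
    q: QuantTable, seed: int, width: float = 0.3, shift: float = 1.8
) -> QuantTable:
    """Perseus-style imputation from a shrunk, down-shifted normal.

    Missing cells in each column are drawn i.i.d. from
    Normal(mu - shift*sigma, (width*sigma)^2) where mu, sigma are the
    column's observed log2 mean and sd.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    was_linear = not q.log2_scale
    work = q.to_log2()
    data = work.data.copy()
    if not data.isna().any().any():
        return q
    _check_imputable(data)
    rng = np.random.default_rng(seed)
    for col in data.columns:
        x = data[col].to_numpy(copy=True)
        miss = np.isnan(x)
        if not miss.any():
            continue
        mu = np.nanmean(x)
        sigma = np.nanstd(x, ddof=1)
        x[miss] = rng.normal(mu - shift * sigma, width * sigma, size=int(miss.sum()))
        data[col] = x
    out = replace(work, data=data)
    return out.to_linear() if was_linear else out


# ---------------------------------------------------------------------------
# Rollup / averaging / normalization


def rollup_and_average(q: QuantTable, design: StudyDesign) -> QuantTable:
    """Sum peptides to proteins (linear scale) and average replicates."""
    work = q.to_linear()
    data = work.data
    if work.level == "peptide":
        assert work.protein_map is not None
        unmapped = data.index.difference(work.protein_map.index)
        if len(unmapped):
            raise ValueError(f"peptides with no protein mapping: {list(unmapped)[:5]}")
        groups = work.protein_map.reindex(data.index)
        data = data.groupby(groups.to_numpy()).sum(min_count=1)
    # replicate average
    data = data.T.groupby(level=["bait", "condition", "fraction"], sort=False).mean().T
    data.columns = pd.MultiIndex.from_tuples(
        list(data.columns), names=("bait", "condition", "fraction")
    )
    return QuantTable(
        data=data, level="protein", log2_scale=False, replicate_averaged=True
    )


def normalize_and_split(q: QuantTable, design: StudyDesign) -> list[ProfileMatrix]:
    """Sum-normalize each protein row across *all* fraction columns, split
    by condition group, then standardize each per-condition row to mean 0,
    sd 1.

    Constant rows (sd 0 within a condition) are dropped with a warning
    rather than failing the run; rows summing to zero are an error.
    """
    if not q.replicate_averaged or q.level != "protein":
        raise ValueError("normalize_and_split expects a protein-level, replicate-averaged table")
    data = q.to_linear().data
    if data.isna().any().any():
        raise ValueError("table must be fully imputed before normalization")

    ordered = []
    for s in design.sample_sets:
        for f in design.fractions:
            col = (s.bait, s.condition, f)
            if col in data.columns:
                ordered.append(col)
    data = data.loc[:, ordered]

    row_sums = data.sum(axis=1)
    if (row_sums == 0).any():
        bad = list(row_sums.index[row_sums == 0])
        raise ValueError(f"protein rows summing to zero: {bad[:5]}")
    normed = data.div(row_sums, axis=0)

    out: list[ProfileMatrix] = []
    for split in design.splits():
        cols = [
            (s.bait, s.condition, f)
            for s in design.sample_sets_for(split)
            for f in design.fractions
        ]
        sub = normed.loc[:, cols]
        sd = sub.std(axis=1, ddof=0)
        const = sd == 0
        if const.any():
            logger.warning(
                "dropping %d constant rows at standardization in %s",
                int(const.sum()),
                split,
            )
            sub, sd = sub.loc[~const], sd[~const]
        z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
        out.append(
            ProfileMatrix(
                values=z, condition=split, sum_normalized=True, standardized=True
            )
        )
    return out


@dataclass
class IngestReport:
    """Row counts surviving each stage, for the run report."""

    stages: list[tuple[str, int]] = field(default_factory=list)

    def record(self, stage: str, n: int) -> None:
        self.stages.append((stage, n))

    def to_dict(self) -> dict:
        return {stage: n for stage, n in self.stages}


def ingest_pipeline(
    q: QuantTable,
    design: StudyDesign,
    seed: int,
    impute: Literal["qrilc", "downshift"] = "qrilc",
    quantile_cut: float = 0.01,
    width: float = 0.3,
    shift: float = 1.8,
) -> tuple[list[ProfileMatrix], IngestReport]:
    """Full chain from a read table to standardized per-condition profiles."""
    report = IngestReport()
    report.record("input", q.n_features)
    q = elution_filter(q, design)
    report.record("elution_filter", q.n_features)
    q = ip_filter(q, design)
    report.record("ip_filter", q.n_features)
    if impute == "qrilc":
        q = impute_qrilc(q, seed=seed, quantile_cut=quantile_cut)
    elif impute == "downshift":
        q = impute_downshift(q, seed=seed, width=width, shift=shift)
    else:
        raise ValueError(f"unknown imputation method {impute!r}")
    q = rollup_and_average(q, design)
    report.record("protein_level", q.n_features)
    profiles = normalize_and_split(q, design)
    for pm in profiles:
        report.record(f"profiles[{pm.condition}]", pm.n_proteins)
    return profiles, report
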