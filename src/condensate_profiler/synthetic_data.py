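"""Synthetic datasets with known ground truth for the granule pipeline.

Three generators emulate the statistical structure the analysis assumes:

* ``generate_quant_dataset`` — multi-fraction IP proteomics intensities
  for planted protein classes (granule members, dual-localized proteins,
  sticky contaminants, background) with multiplicative log-normal noise
  and left-censored (intensity-dependent) missingness encoded as zeros;
* ``generate_transcript_set`` — transcript sequences with controlled
  UTR/CDS lengths, base composition and planted polyA tracts;
* ``generate_ripseq_counts`` — negative-binomial IP-vs-total count
  matrices with a planted fold-change in a subset of genes.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .design import SampleSet, StudyDesign, granule_ip_design
from .quant_ingest import QuantTable, _columns_index
from .seq_features import CountMatrix, TranscriptRecord

PROTEIN_CLASSES = (
    "seed_A",
    "seed_B",
    "granule_A",
    "granule_B",
    "dual",
    "contaminant",
    "background",
)

#: planted label -> granule label the pipeline should recover
EXPECTED_LABEL = {
    "seed_A": "granule_A",
    "seed_B": "granule_B",
    "granule_A": "granule_A",
    "granule_B": "granule_B",
    "dual": "both",
    "contaminant": "none",
    "background": "none",
}

DEFAULT_CLASS_COUNTS = {
    "seed_A": 1,
    "seed_B": 1,
    "granule_A": 20,
    "granule_B": 20,
    "dual": 10,
    "contaminant": 0,
    "background": 348,
}


@dataclass
class NoiseSpec:
    """Multiplicative noise and left-censored missingness.

    ``sd`` is the standard deviation of log-normal multiplicative noise
    (natural-log scale). Missingness is MNAR: a cell with log2-intensity
    ``x`` is censored with probability ``expit(-slope * (x - midpoint))``,
    which decreases with intensity; ``midpoint = None`` disables it.
    """

    sd: float = 0.3
    missing_midpoint: float | None = None
    missing_slope: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.missing_slope <= 0:
            raise ValueError("missingness slope must be positive")

    def missing_prob(self, log2_intensity: np.ndarray) -> np.ndarray:
        if self.missing_midpoint is None:
            return np.zeros_like(log2_intensity)
        return expit(-self.missing_slope * (log2_intensity - self.missing_midpoint))


def calibrate_missing_midpoint(
    log2_intensities: np.ndarray, target_rate: float, slope: float = 1.0
) -> float:
    """Midpoint such that the *expected* marginal missing fraction over the
    given intensities equals ``target_rate``."""
    if not 0 < target_rate < 1:
        raise ValueError("target rate must be in (0, 1)")
    x = np.asarray(log2_intensities, dtype=float).ravel()

    def excess(mid: float) -> float:
        return float(expit(-slope * (x - mid)).mean()) - target_rate

    lo, hi = x.min() - 50.0, x.max() + 50.0
    return float(brentq(excess, lo, hi, xtol=1e-9))


@dataclass
class TruthLabels:
    """Ground-truth class labels for simulated features."""

    protein_class: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    transcript_group: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    gene_enriched: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))

    def expected_granule_label(self) -> pd.Series:
        return self.protein_class.map(EXPECTED_LABEL)

    def write_tsv(self, path) -> None:
        parts = []
        for name, s in (
            ("protein_class", self.protein_class),
            ("transcript_group", self.transcript_group),
            ("gene_enriched", self.gene_enriched),
        ):
            if len(s):
                parts.append(
                    pd.DataFrame({"id": s.index, "field": name, "value": s.to_numpy()})
                )
        pd.concat(parts, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Proteome simulation

# relative elution weight across (IP, P, S, T, U); "bait" applies in the
# tagged sample set matching the class's granule, "other" elsewhere
_TEMPLATE_ROLES: dict[str, dict[str, tuple[float, ...]]] = {
    "granule_A": {
        "bait": (0.35, 0.28, 0.08, 0.15, 0.14),
        "other": (0.01, 0.28, 0.18, 0.25, 0.28),
    },
    "granule_B": {
        "bait": (0.35, 0.28, 0.08, 0.15, 0.14),
        "other": (0.01, 0.28, 0.18, 0.25, 0.28),
    },
    "contaminant": {
        "other": (0.30, 0.12, 0.18, 0.20, 0.20),
    },
    "background": {
        "other": (0.015, 0.08, 0.36, 0.37, 0.175),
    },
}


@dataclass
class ProteomeSimSpec:
    """Configuration of the fractionation-proteomics simulation."""

    class_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    bait_a: str = "dcp1_myc"
    bait_b: str = "pbp1_myc"
    dual_weight: float = 0.5
    abundance_log2_mean: float = 23.0
    abundance_log2_sd: float = 1.5
    target_missing_rate: float | None = 0.10

    def __post_init__(self) -> None:
        unknown = set(self.class_counts) - set(PROTEIN_CLASSES)
        if unknown:
            raise ValueError(f"unknown protein classes: {sorted(unknown)}")
        if any(n < 0 for n in self.class_counts.values()):
            raise ValueError("class counts must be non-negative")
        if not 0 <= self.dual_weight <= 1:
            raise ValueError("dual weight must lie in [0, 1]")


def default_profile_templates() -> dict[str, dict[str, tuple[float, ...]]]:
    """Editable copy of the built-in class -> role -> fraction templates."""
    return {k: dict(v) for k, v in _TEMPLATE_ROLES.items()}


def _class_weights(
    cls: str,
    sample_set: SampleSet,
    spec: ProteomeSimSpec,
    templates: dict[str, dict[str, tuple[float, ...]]],
    n_fractions: int,
) -> np.ndarray:
    def role_of(granule_cls: str) -> str:
        bait = spec.bait_a if granule_cls == "granule_A" else spec.bait_b
        return "bait" if (sample_set.tagged and sample_set.bait == bait) else "other"

    def tmpl(c: str, role: str) -> np.ndarray:
        t = templates.get(c)
        if t is None or role not in t:
            raise KeyError(f"no template for class {c!r} role {role!r}")
        w = np.asarray(t[role], dtype=float)
        if w.size != n_fractions or (w < 0).any():
            raise ValueError(f"template for {c!r}/{role!r} must be {n_fractions} non-negative values")
        return w

    if cls in ("granule_A", "seed_A"):
        return tmpl("granule_A", role_of("granule_A"))
    if cls in ("granule_B", "seed_B"):
        return tmpl("granule_B", role_of("granule_B"))
    if cls == "dual":
        w = spec.dual_weight
        return w * tmpl("granule_A", role_of("granule_A")) + (1 - w) * tmpl(
            "granule_B", role_of("granule_B")
        )
    if cls == "contaminant":
        return tmpl("contaminant", "other")
    if cls == "background":
        return tmpl("background", "other")
    raise KeyError(f"unknown class {cls!r}")


def generate_quant_dataset(
    design: StudyDesign | None = None,
    spec: ProteomeSimSpec | None = None,
    templates: dict[str, dict[str, tuple[float, ...]]] | None = None,
    seed: int = 0,
) -> tuple[QuantTable, TruthLabels]:
    """Simulate a protein-level quantification table with ground truth.

    Each protein draws a base abundance (log2-normal) and, per sample
    column, an intensity = abundance x class/fraction template weight x
    log-normal noise. Missingness is applied per cell as a decreasing
    logistic function of log2 intensity and encoded as NaN in the
    returned table (zero when written to disk). The two seed (marker)
    proteins are by construction always detected in their own tagged
    elution columns.
    """
    design = design or granule_ip_design()
    spec = spec or ProteomeSimSpec()
    templates = templates or _TEMPLATE_ROLES
    if design.n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)

    ids: list[str] = []
    classes: list[str] = []
    for cls in PROTEIN_CLASSES:
        n = spec.class_counts.get(cls, 0)
        if cls.startswith("seed_") and n not in (0, 1):
            raise ValueError(f"{cls} count must be 0 or 1")
        for i in range(n):
            ids.append(cls if cls.startswith("seed_") else f"{cls}_{i:04d}")
            classes.append(cls)
    if not ids:
        raise ValueError("no proteins requested")

    keys = design.sample_keys()
    n_prot, n_cols = len(ids), len(keys)
    nf = len(design.fractions)

    abundance = 2.0 ** rng.normal(
        spec.abundance_log2_mean, spec.abundance_log2_sd, size=n_prot
    )
    weights = np.empty((n_prot, n_cols))
    set_of_key = [
        s for s in design.sample_sets for _ in design.fractions
        for _ in range(design.n_replicates)
    ]
    frac_of_key = [k.fraction for k in keys]
    for p, cls in enumerate(classes):
        for j, (sset, frac) in enumerate(zip(set_of_key, frac_of_key)):
            w = _class_weights(cls, sset, spec, templates, nf)
            weights[p, j] = w[design.fractions.index(frac)]

    noise = (
        np.exp(rng.normal(0.0, spec.noise.sd, size=(n_prot, n_cols)))
        if spec.noise.sd > 0
        else np.ones((n_prot, n_cols))
    )
    intensity = abundance[:, None] * weights * noise

    # missingness: MNAR logistic in log2 intensity
    noise_spec = spec.noise
    if spec.target_missing_rate is not None and noise_spec.missing_midpoint is None:
        positive = intensity[intensity > 0]
        mid = calibrate_missing_midpoint(
            np.log2(positive), spec.target_missing_rate, noise_spec.missing_slope
        )
        noise_spec = NoiseSpec(
            sd=noise_spec.sd,
            missing_midpoint=mid,
            missing_slope=noise_spec.missing_slope,
            seed=noise_spec.seed,
        )
    with np.errstate(divide="ignore"):
        log2_i = np.where(intensity > 0, np.log2(np.maximum(intensity, 1e-300)), -np.inf)
    p_miss = noise_spec.missing_prob(log2_i)
    missing = rng.random((n_prot, n_cols)) < p_miss

    # the bait never goes missing in its own elution
    for p, cls in enumerate(classes):
        if cls not in ("seed_A", "seed_B"):
            continue
        bait = spec.bait_a if cls == "seed_A" else spec.bait_b
        for j, (sset, frac) in enumerate(zip(set_of_key, frac_of_key)):
            if sset.tagged and sset.bait == bait and frac == design.fractions[0]:
                missing[p, j] = False

    data = pd.DataFrame(
        np.where(missing, np.nan, intensity),
        index=pd.Index(ids, name="id"),
        columns=_columns_index(keys),
    )
    truth = TruthLabels(protein_class=pd.Series(classes, index=ids, name="class"))
    return QuantTable(data=data, level="protein"), truth


# ---------------------------------------------------------------------------
# Transcript simulation


@dataclass
class TranscriptGroupSpec:
    """One transcript group: sizes, composition and planted polyA tracts.

    ``region_lengths`` gives mean (5'UTR, CDS, 3'UTR) lengths; each is
    drawn log-normally with coefficient of variation ``length_cv`` (0 =
    fixed). ``base_composition`` maps A/C/G/T to target fractions.
    ``polya_tract_lengths``: lengths of A-runs planted per transcript; if
    given, the planted runs are the *only* runs >= ``min_run``.
    """

    name: str
    n: int
    region_lengths: tuple[float, float, float] = (100.0, 1200.0, 150.0)
    length_cv: float = 0.0
    base_composition: dict[str, float] = field(
        default_factory=lambda: {"A": 0.31, "C": 0.19, "G": 0.20, "T": 0.30}
    )
    polya_tract_lengths: Sequence[int] | None = None
    min_run: int = 8

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("group size must be positive")
        comp = {b.upper(): f for b, f in self.base_composition.items()}
        if set(comp) - set("ACGT"):
            raise ValueError("composition restricted to A/C/G/T")
        vals = np.array([comp.get(b, 0.0) for b in "ACGT"])
        if (vals < 0).any():
            raise ValueError("negative residual base mass in composition")
        if abs(vals.sum() - 1.0) > 1e-6:
            raise ValueError("base composition must sum to 1")
        self.base_composition = dict(zip("ACGT", vals))


def _break_long_runs(seq: np.ndarray, min_run: int, rng: np.random.Generator) -> None:
    """Destroy accidental A-runs of length >= min_run in place."""
    non_a = np.array(list("CGT"))
    i, n = 0, seq.size
    while i < n:
        if seq[i] != "A":
            i += 1
            continue
        j = i
        while j < n and seq[j] == "A":
            j += 1
        if j - i >= min_run:
            for k in range(i + min_run - 1, j, min_run - 1):
                seq[k] = rng.choice(non_a)
        i = j


def _plant_tracts(
    seq: np.ndarray, lengths: Sequence[int], min_run: int, rng: np.random.Generator
) -> None:
    """Plant maximal A-runs of the given lengths at non-adjacent positions."""
    n = seq.size
    need = sum(lengths) + (len(lengths) + 1)  # flanking non-A separators
    if any(ln > n - 2 for ln in lengths) or need > n:
        raise ValueError(
            f"cannot place tracts of lengths {list(lengths)} in a sequence of length {n}"
        )
    non_a = np.array(list("CGT"))
    placed: list[tuple[int, int]] = []
    for ln in sorted(lengths, reverse=True):
        for _ in range(10_000):
            start = int(rng.integers(1, n - ln))  # keep room for flanks
            span = (start - 1, start + ln + 1)
            if all(span[1] <= s or span[0] >= e for s, e in placed):
                placed.append(span)
                seq[start : start + ln] = "A"
                seq[start - 1] = rng.choice(non_a)
                if start + ln < n:
                    seq[start + ln] = rng.choice(non_a)
                break
        else:
            raise ValueError("could not place all requested tracts without overlap")


def generate_transcript_set(
    group_specs: Sequence[TranscriptGroupSpec], seed: int = 0
) -> tuple[list[TranscriptRecord], pd.DataFrame, TruthLabels]:
    """Simulate transcript groups; returns records, an annotation table
    (1-based inclusive coordinates in the exported form) and truth labels."""
    if not group_specs:
        raise ValueError("need at least one group spec")
    rng = np.random.default_rng(seed)
    records: list[TranscriptRecord] = []
    groups: dict[str, str] = {}
    rows = []
    bases = np.array(list("ACGT"))
    for gspec in group_specs:
        probs = np.array([gspec.base_composition[b] for b in "ACGT"])
        for i in range(gspec.n):
            tid = f"{gspec.name}_{i:04d}"
            lens = []
            for mean in gspec.region_lengths:
                if gspec.length_cv > 0 and mean > 0:
                    sigma = np.sqrt(np.log1p(gspec.length_cv**2))
                    mu = np.log(mean) - sigma**2 / 2
                    lens.append(max(0, int(round(rng.lognormal(mu, sigma)))))
                else:
                    lens.append(int(round(mean)))
            u5, cds, u3 = lens
            total = u5 + cds + u3
            if total == 0:
                raise ValueError(f"zero-length transcript in group {gspec.name}")
            seq = rng.choice(bases, size=total, p=probs)
            if gspec.polya_tract_lengths is not None:
                _break_long_runs(seq, gspec.min_run, rng)
                _plant_tracts(seq, gspec.polya_tract_lengths, gspec.min_run, rng)
            records.append(
                TranscriptRecord(tid, "".join(seq), u5, cds, u3)
            )
            groups[tid] = gspec.name
            rows.append({"id": tid, "utr5_len": u5, "cds_len": cds, "utr3_len": u3})
    annotation = pd.DataFrame(rows).set_index("id")
    truth = TruthLabels(transcript_group=pd.Series(groups, name="group"))
    return records, annotation, truth


def write_fasta(records: Sequence[TranscriptRecord], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write(
        [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# RIP-seq count simulation


@dataclass
class RipseqSimSpec:
    """Negative-binomial IP-vs-total simulation with planted enrichment."""

    n_genes: int = 2000
    frac_enriched: float = 0.1
    log2_effect: float = 1.0
    dispersion: float = 0.1
    n_ip: int = 3
    n_total: int = 3
    size_factors: Sequence[float] | None = None
    base_mean_log2: float = 7.0
    base_sd_log2: float = 1.5

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("NB dispersion must be positive")
        if not np.isfinite(self.log2_effect):
            raise ValueError("effect size must be finite")
        if not 0 <= self.frac_enriched <= 1:
            raise ValueError("enriched fraction must lie in [0, 1]")
        n_lib = self.n_ip + self.n_total
        if self.size_factors is None:
            self.size_factors = tuple([1.0] * n_lib)
        elif len(self.size_factors) != n_lib:
            raise ValueError(f"need {n_lib} size factors")


def generate_ripseq_counts(
    spec: RipseqSimSpec | None = None, seed: int = 0
) -> tuple[CountMatrix, TruthLabels]:
    """Simulate gamma-Poisson (NB) counts; enriched genes carry the
    planted log2 effect in IP libraries only."""
    spec = spec or RipseqSimSpec()
    rng = np.random.default_rng(seed)
    n = spec.n_genes
    genes = [f"gene_{i:05d}" for i in range(n)]
    n_enriched = int(round(spec.frac_enriched * n))
    enriched = np.zeros(n, dtype=bool)
    enriched[rng.choice(n, size=n_enriched, replace=False)] = True

    base = 2.0 ** rng.normal(spec.base_mean_log2, spec.base_sd_log2, size=n)
    libs = [f"IP_rep{i+1}" for i in range(spec.n_ip)] + [
        f"total_rep{i+1}" for i in range(spec.n_total)
    ]
    classes = ["IP"] * spec.n_ip + ["total"] * spec.n_total
    sf = np.asarray(spec.size_factors, dtype=float)

    mu = np.empty((n, len(libs)))
    fold = np.where(enriched, 2.0**spec.log2_effect, 1.0)
    for j, cls in enumerate(classes):
        mu[:, j] = base * (fold if cls == "IP" else 1.0) * sf[j]
    shape = 1.0 / spec.dispersion
    lam = rng.gamma(shape, mu * spec.dispersion)
    counts = rng.poisson(lam)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=libs),
        library_class=pd.Series(classes, index=libs),
    )
    truth = TruthLabels(gene_enriched=pd.Series(enriched, index=genes, name="enriched"))
    return cm, truth
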