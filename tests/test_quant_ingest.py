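"""Tests for reading, filtering, imputation and profile assembly."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reference_impl import censored_tail_mean

from condensate_profiler.design import (
    SampleSet,
    StudyDesign,
    granule_ip_design,
    format_generic_column,
    parse_generic_column,
)
from condensate_profiler.quant_ingest import (
    QuantTable,
    elution_filter,
    impute_downshift,
    impute_qrilc,
    ingest_pipeline,
    ip_filter,
    normalize_and_split,
    read_quant_table,
    rollup_and_average,
    _columns_index,
)
from condensate_profiler.synthetic_data import generate_quant_dataset


def small_design(n_replicates=2):
    return StudyDesign(
        sample_sets=[
            SampleSet("tagA", "cond1", True),
            SampleSet("untagged", "cond1", False),
        ],
        n_replicates=n_replicates,
    )


def make_table(design, values, ids=None):
    keys = design.sample_keys()
    arr = np.asarray(values, dtype=float)
    ids = ids or [f"prot{i}" for i in range(arr.shape[0])]
    return QuantTable(
        data=pd.DataFrame(arr, index=pd.Index(ids, name="id"),
                          columns=_columns_index(keys)),
        level="protein",
    )


class TestReaders:
    def test_generic_round_trip(self, design, tmp_path, default_dataset):
        quant, _ = default_dataset
        quant.write_tsv(tmp_path / "q.tsv")
        back = read_quant_table(tmp_path / "q.tsv", "generic_tsv", design)
        pd.testing.assert_frame_equal(quant.data, back.data, check_names=False)

    def test_zero_reads_as_missing(self, tmp_path):
        design = small_design()
        cols = [format_generic_column(k) for k in design.sample_keys()]
        tsv = "id\t" + "\t".join(cols) + "\nP1\t" + "\t".join(["0"] + ["5"] * 19)
        path = tmp_path / "q.tsv"
        path.write_text(tsv + "\n")
        q = read_quant_table(path, "generic_tsv", design)
        assert np.isnan(q.data.iloc[0, 0])
        assert (q.data.iloc[0, 1:] == 5).all()

    def test_maxquant_flagged_rows_removed(self, tmp_path):
        design = small_design()
        samples = {f"S{i}": format_generic_column(k)
                   for i, k in enumerate(design.sample_keys())}
        header = (
            ["Majority protein IDs", "Reverse", "Potential contaminant",
             "Only identified by site"]
            + [f"LFQ intensity {s}" for s in samples]
        )
        rows = []
        for i in range(10):
            flag = "+" if i == 3 else ""
            rows.append([f"P{i};ALT{i}", flag, "", ""] + ["7"] * len(samples))
        path = tmp_path / "pg.tsv"
        path.write_text(
            "\t".join(header) + "\n"
            + "\n".join("\t".join(r) for r in rows) + "\n"
        )
        q = read_quant_table(path, "maxquant_proteingroups", design,
                             column_map=samples)
        assert q.n_features == 9
        assert "P3" not in q.data.index
        assert "P0" in q.data.index  # first of the semicolon group

    def test_unmapped_column_errors(self, tmp_path):
        design = small_design()
        path = tmp_path / "q.tsv"
        path.write_text("id\tnonsense|x|IP|rep1\nP1\t3\n")
        with pytest.raises(ValueError, match="not in design|cannot parse"):
            read_quant_table(path, "generic_tsv", design)

    def test_duplicate_ids_error(self, tmp_path):
        design = small_design()
        cols = [format_generic_column(k) for k in design.sample_keys()]
        body = "\t".join(["3"] * len(cols))
        path = tmp_path / "q.tsv"
        path.write_text(
            "id\t" + "\t".join(cols) + f"\nP1\t{body}\nP1\t{body}\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_quant_table(path, "generic_tsv", design)

    def test_column_key_round_trip(self):
        for k in granule_ip_design().sample_keys():
            assert parse_generic_column(format_generic_column(k)) == k


class TestFilters:
    def test_untagged_only_signal_removed(self):
        design = small_design()
        # columns: tagA IP r1 r2, P, S, T, U then untagged ...
        vals = np.full((1, 20), np.nan)
        vals[0, 10] = 100.0  # untagged IP rep1
        q = make_table(design, vals)
        assert ip_filter(q, design).n_features == 0
        assert elution_filter(q, design).n_features == 1

    def test_single_tagged_ip_detection_suffices(self):
        design = small_design()
        vals = np.full((1, 20), np.nan)
        vals[0, 1] = 42.0  # tagA IP rep2
        q = make_table(design, vals)
        assert ip_filter(q, design).n_features == 1

    def test_synthetic_retained_set_matches_truth(self, design, default_dataset):
        """The IP filter keeps exactly the proteins with at least one
        surviving tagged-elution measurement."""
        quant, _ = default_dataset
        kept = ip_filter(elution_filter(quant, design), design)
        tagged = {(s.bait, s.condition) for s in design.sample_sets if s.tagged}
        ip_cols = [
            c for c in quant.data.columns
            if (c[0], c[1]) in tagged and c[2] == "IP"
        ]
        expected = quant.data[ip_cols].notna().any(axis=1)
        assert set(kept.data.index) == set(quant.data.index[expected])


class TestImputation:
    def _censored_column_table(self, n=2000, cut=19.0, seed=123):
        rng = np.random.default_rng(seed)
        design = small_design(n_replicates=1)
        full = rng.normal(20.0, 1.0, size=(n, 10))
        censored = np.where(full < cut, np.nan, full)
        q = QuantTable(
            data=pd.DataFrame(censored, index=[f"p{i}" for i in range(n)],
                              columns=_columns_index(design.sample_keys())),
            level="protein",
            log2_scale=True,
        )
        return q, full

    def test_no_missing_is_identity(self):
        design = small_design()
        vals = np.arange(1.0, 41.0).reshape(2, 20)
        q = make_table(design, vals)
        assert impute_qrilc(q, seed=0).data.equals(q.data)
        assert impute_downshift(q, seed=0).data.equals(q.data)

    def test_observed_cells_never_altered(self):
        q, _ = self._censored_column_table()
        out = impute_qrilc(q, seed=0)
        mask = q.data.notna()
        pd.testing.assert_frame_equal(out.data[mask], q.data[mask])

    def test_qrilc_matches_censored_tail_mean(self):
        """Imputed values reproduce the conditional mean of the censored
        left tail of a N(20, 1) column censored below 19 (numeric oracle)."""
        q, _ = self._censored_column_table(n=2000, cut=19.0)
        out = impute_qrilc(q, seed=7)
        oracle = censored_tail_mean(20.0, 1.0, 19.0)
        imputed = out.data.to_numpy()[q.data.isna().to_numpy()]
        assert abs(imputed.mean() - oracle) < 0.1

    def test_qrilc_truncation_bound(self):
        """When the quantile cut lies below the observed minimum's plotting
        position, every imputed value falls below the observed minimum."""
        n, n_miss = 1000, 200
        design = small_design(n_replicates=1)
        # observed values placed exactly at their normal plotting positions,
        # so the quantile regression recovers mu=20, sigma=1 exactly
        ranks = np.arange(n_miss + 1, n + 1)
        z = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
        col = np.concatenate([np.full(n_miss, np.nan), 20.0 + z])
        data = pd.DataFrame(
            np.tile(col[:, None], (1, 10)),
            index=[f"p{i}" for i in range(n)],
            columns=_columns_index(design.sample_keys()),
        )
        q = QuantTable(data=data, level="protein", log2_scale=True)
        out = impute_qrilc(q, seed=2, quantile_cut=0.0001)
        obs_min = np.nanmin(col)
        imputed = out.data.to_numpy()[np.isnan(data.to_numpy())]
        assert imputed.max() < obs_min

    def test_qrilc_refuses_sparse_columns(self):
        design = small_design(n_replicates=1)
        vals = np.full((6, 10), np.nan)
        vals[:3, :] = 20.0  # only 3 observed per column
        q = QuantTable(
            data=pd.DataFrame(vals, index=[f"p{i}" for i in range(6)],
                              columns=_columns_index(design.sample_keys())),
            level="protein", log2_scale=True,
        )
        with pytest.raises(ValueError, match="fewer than 5"):
            impute_qrilc(q, seed=0)

    def test_downshift_moments(self):
        """5000 missing cells in a mu=25, sigma=2 column are imputed with
        mean 25 - 1.8*2 = 21.4 and sd 0.3*2 = 0.6."""
        rng = np.random.default_rng(77)
        design = small_design(n_replicates=1)
        observed = rng.normal(25.0, 2.0, size=2000)
        col = np.concatenate([observed, np.full(5000, np.nan)])
        data = pd.DataFrame(
            np.tile(col[:, None], (1, 10)),
            index=[f"p{i}" for i in range(col.size)],
            columns=_columns_index(design.sample_keys()),
        )
        q = QuantTable(data=data, level="protein", log2_scale=True)
        out = impute_downshift(q, seed=3)
        first = out.data.iloc[:, 0]
        imputed = first[col != col]  # NaN mask
        mu_hat, sd_hat = observed.mean(), observed.std(ddof=1)
        assert abs(imputed.mean() - (mu_hat - 1.8 * sd_hat)) < 0.1
        assert abs(imputed.std(ddof=1) - 0.3 * sd_hat) < 0.05
        assert abs(imputed.mean() - 21.4) < 0.2
        assert abs(imputed.std(ddof=1) - 0.6) < 0.1

    def test_downshift_rejects_bad_width(self):
        q, _ = self._censored_column_table(n=100, cut=19.0)
        with pytest.raises(ValueError, match="width"):
            impute_downshift(q, seed=0, width=0.0)

    def test_imputation_deterministic_given_seed(self):
        q, _ = self._censored_column_table()
        a = impute_qrilc(q, seed=9).data
        b = impute_qrilc(q, seed=9).data
        pd.testing.assert_frame_equal(a, b)
        c = impute_qrilc(q, seed=10).data
        assert not a.equals(c)


class TestRollupAndNormalize:
    def test_peptide_sum_and_replicate_mean(self):
        design = small_design(n_replicates=3)
        keys = design.sample_keys()
        peptides = pd.DataFrame(
            np.zeros((2, len(keys))),
            index=pd.Index(["pep1", "pep2"], name="id"),
            columns=_columns_index(keys),
        )
        peptides.iloc[0, :] = 1.0
        peptides.iloc[1, :] = 3.0
        # make replicates of the first fraction (2, 4, 6) for averaging
        peptides.iloc[:, 0:3] = np.array([[1, 2, 3], [1, 2, 3]])
        q = QuantTable(
            data=peptides, level="peptide",
            protein_map=pd.Series({"pep1": "P1", "pep2": "P1"}),
        )
        out = rollup_and_average(q, design)
        assert out.n_features == 1
        assert out.data.iloc[0, 0] == pytest.approx(4.0)  # mean of (2,4,6)
        assert out.data.iloc[0, 1] == pytest.approx(4.0)  # 1 + 3 elsewhere

    def test_one_peptide_per_protein_is_identity(self):
        design = small_design()
        vals = np.arange(1.0, 41.0).reshape(2, 20)
        q = QuantTable(
            data=make_table(design, vals).data,
            level="peptide",
            protein_map=pd.Series({"prot0": "A", "prot1": "B"}),
        )
        out = rollup_and_average(q, design)
        merged = q.data.T.groupby(level=["bait", "condition", "fraction"],
                                  sort=False).mean().T
        np.testing.assert_allclose(out.data.to_numpy(), merged.to_numpy())

    def test_profile_dimensionality_matches_design(self, design, default_dataset):
        """The two-marker design yields 15 untreated and 20 glucose-depleted
        profile values per protein."""
        quant, _ = default_dataset
        profiles, _ = ingest_pipeline(quant, design, seed=0)
        dims = {pm.condition: pm.dimensionality for pm in profiles}
        assert dims == {"untreated": 15, "glucose_depleted": 20}

    def test_rows_standardized_and_sum_normalized(self, design, default_dataset):
        quant, _ = default_dataset
        profiles, _ = ingest_pipeline(quant, design, seed=0)
        for pm in profiles:
            z = pm.values.to_numpy()
            np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
            np.testing.assert_allclose(z.std(axis=1), 1.0, atol=1e-9)

    def test_pre_split_rows_sum_to_one(self, design, clean_dataset):
        quant, _ = clean_dataset
        q = rollup_and_average(quant, design)
        normed = q.data.div(q.data.sum(axis=1), axis=0)
        np.testing.assert_allclose(normed.sum(axis=1), 1.0, atol=1e-9)

    def test_row_rescaling_invariance(self, design, clean_dataset):
        """Multiplying a protein's row by a constant leaves its
        standardized profile unchanged."""
        quant, _ = clean_dataset
        q = rollup_and_average(quant, design)
        scaled = q.data.copy()
        scaled.iloc[0] *= 37.5
        q2 = QuantTable(data=scaled, level="protein", replicate_averaged=True)
        a = normalize_and_split(q, design)[0].values.iloc[0].to_numpy()
        b = normalize_and_split(q2, design)[0].values.iloc[0].to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_zero_row_errors(self, design, clean_dataset):
        quant, _ = clean_dataset
        q = rollup_and_average(quant.copy(), design)
        data = q.data.copy()
        data.iloc[0] = 0.0
        bad = QuantTable(data=data, level="protein", replicate_averaged=True)
        with pytest.raises(ValueError, match="summing to zero"):
            normalize_and_split(bad, design)
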