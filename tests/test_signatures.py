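"""Time-series summarization, consensus signatures, organism attribution."""

import numpy as np
import pandas as pd
import pytest

from terroirseq import (
    CountTable,
    SampleMetadata,
    ValidationError,
    consensus_signature,
    organism_attribution,
    summarize_timeseries,
)
from terroirseq.signatures import (
    ATTRIBUTES,
    fermentation_labels,
    positive_class_features,
    run_model,
)


def rna_tables_for(series: dict[str, list[int]], timepoints=(2.0, 6.0, 16.0)):
    """Single-fermentation transcript tables from per-gene count series."""
    tables = {}
    genes = list(series)
    for k, tp in enumerate(timepoints):
        counts = pd.DataFrame(
            {"S1-2017-T1-%gh" % tp: [series[g][k] for g in genes]}, index=genes
        )
        tables[tp] = CountTable(
            counts=counts,
            marker="mRNA",
            organism=pd.Series({g: "Saccharomyces cerevisiae" for g in genes}),
        )
    return tables


def meta_for(timepoints=(2.0, 6.0, 16.0)):
    rows = {
        "S1-2017-T1-%gh" % tp: {
            "site": "S1",
            "region": "R1",
            "vintage": "2017",
            "tank": "T1",
            "timepoint_hours": tp,
        }
        for tp in timepoints
    }
    return SampleMetadata(pd.DataFrame.from_dict(rows, orient="index"))


class TestSummarize:
    def test_five_attribute_closed_form(self):
        # one gene at all reads -> normalized series [1,1,1]; use two genes
        tables = rna_tables_for({"g1": [2, 4, 6], "g2": [8, 6, 4]})
        feats = summarize_timeseries(tables, meta_for())
        row = feats.loc["S1|2017|T1"]
        series = np.array([0.2, 0.4, 0.6])
        assert row[("g1", "mean")] == pytest.approx(series.mean())
        assert row[("g1", "min")] == pytest.approx(0.2)
        assert row[("g1", "max")] == pytest.approx(0.6)
        assert row[("g1", "total")] == pytest.approx(1.2)
        assert row[("g1", "sd")] == pytest.approx(series.std(ddof=1))

    def test_constant_series_zero_sd(self):
        tables = rna_tables_for({"g1": [5, 5, 5], "g2": [5, 5, 5]})
        feats = summarize_timeseries(tables, meta_for())
        row = feats.loc["S1|2017|T1"]
        assert row[("g1", "sd")] == 0
        assert row[("g1", "mean")] == row[("g1", "min")] == row[("g1", "max")] == 0.5

    def test_all_zero_gene_all_zero_attributes(self):
        tables = rna_tables_for({"g1": [0, 0, 0], "g2": [5, 5, 5]})
        feats = summarize_timeseries(tables, meta_for())
        for attr in ATTRIBUTES:
            assert feats.loc["S1|2017|T1", ("g1", attr)] == 0

    def test_single_timepoint_rejected(self):
        tables = rna_tables_for({"g1": [2], "g2": [3]}, timepoints=(2.0,))
        with pytest.raises(ValidationError, match="single timepoint"):
            summarize_timeseries(tables, meta_for(timepoints=(2.0,)))

    def test_min_mean_max_ordering_invariant(self, rna_feature_matrix):
        feats = rna_feature_matrix
        genes = feats.columns.get_level_values("gene").unique()[:50]
        for g in genes:
            assert (feats[(g, "min")] <= feats[(g, "mean")] + 1e-12).all()
            assert (feats[(g, "mean")] <= feats[(g, "max")] + 1e-12).all()
            assert (feats[(g, "sd")] >= 0).all()


class TestConsensus:
    def _toy_features(self, seed=0, n_per_class=8):
        rng = np.random.default_rng(seed)
        # gene g1 separates the two sites cleanly; g2 is noise
        n = n_per_class * 2
        labels, rows, idx = [], [], []
        for i in range(n):
            site = "S1" if i < n_per_class else "S2"
            vintage = "2017" if i % 2 == 0 else "2019"
            idx.append(f"{site}|{vintage}|T{i}")
            labels.append(site)
            signal = (1.0 if site == "S1" else -1.0) + rng.normal(0, 0.1)
            rows.append([signal, rng.normal()])
        feats = pd.DataFrame(
            rows,
            index=idx,
            columns=pd.MultiIndex.from_tuples(
                [("g1", "mean"), ("g2", "mean")], names=["gene", "attribute"]
            ),
        )
        return feats, pd.Series(labels, index=idx, name="site")

    def test_perfect_gene_in_signature_noise_gene_out(self):
        feats, labels = self._toy_features()
        sig, models = consensus_signature(
            feats, labels, scheme="split70", n_seeds=3, base_seed=0, n_trees=60
        )
        assert "g1" in sig.all_genes()
        assert "g2" not in sig.all_genes()
        assert all(m.accuracy == 1.0 for m in models)

    def test_strict_intersection_excludes_gene_missing_once(self):
        feats, labels = self._toy_features()
        results = [
            run_model(feats, labels, scheme="split70", seed=s, n_trees=40)
            for s in range(3)
        ]
        per_seed = [positive_class_features(r) for r in results]
        # forge one seed that lacks g1 for every class
        forged = [
            {cls: {k: v for k, v in d.items() if k[0] != "g1"} for cls, d in per_seed[0].items()}
        ] + per_seed[1:]
        survivors = set.intersection(
            *[{g for d in ps.values() for (g, _) in d} for ps in forged]
        )
        assert "g1" not in survivors

    def test_signature_size_non_increasing_in_seeds(self, rna_feature_matrix, large_effect_study):
        feats = rna_feature_matrix
        labels = fermentation_labels(feats, large_effect_study.metadata, "site")
        labels.name = "site"
        sig3, _ = consensus_signature(
            feats, labels, n_seeds=3, base_seed=0, n_trees=150, vita_trees=80
        )
        sig5, _ = consensus_signature(
            feats, labels, n_seeds=5, base_seed=0, n_trees=150, vita_trees=80
        )
        for cls in sig5.signatures:
            assert sig5.genes(cls) <= sig3.genes(cls)

    def test_fewer_than_two_seeds_rejected(self):
        feats, labels = self._toy_features()
        with pytest.raises(ValidationError):
            consensus_signature(feats, labels, n_seeds=1)


class TestOrganismAttribution:
    def test_equal_split(self):
        imp = pd.Series({"g1": 2.0, "g2": 2.0})
        orgs = pd.Series({"g1": "A", "g2": "B"})
        out = organism_attribution(imp, orgs)
        assert out["A"] == pytest.approx(50.0) and out["B"] == pytest.approx(50.0)

    def test_three_to_one_split_with_negative_truncation(self):
        imp = pd.Series({"g1": 3.0, "g2": 1.0, "g3": -5.0})
        orgs = pd.Series({"g1": "A", "g2": "B", "g3": "B"})
        out = organism_attribution(imp, orgs)
        assert out["A"] == pytest.approx(75.0) and out["B"] == pytest.approx(25.0)
        assert out.sum() == pytest.approx(100.0)

    def test_single_organism_everything(self):
        out = organism_attribution(
            pd.Series({"g1": 1.0}), pd.Series({"g1": "Only"})
        )
        assert out["Only"] == pytest.approx(100.0)

    def test_all_zero_importance_flagged(self):
        with pytest.raises(ValidationError):
            organism_attribution(
                pd.Series({"g1": 0.0}), pd.Series({"g1": "A"})
            )


class TestLabels:
    def test_fermentation_labels_site_region_vintage(self, rna_feature_matrix, large_effect_study):
        feats = rna_feature_matrix
        meta = large_effect_study.metadata
        sites = fermentation_labels(feats, meta, "site")
        regions = fermentation_labels(feats, meta, "region")
        site_region = meta.frame.groupby("site")["region"].first()
        for ferm in feats.index[:10]:
            assert sites[ferm] == ferm.split("|")[0]
            assert regions[ferm] == site_region[sites[ferm]]
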