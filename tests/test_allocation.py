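"""Allocation patterns: proportions, class binning, climate correlations."""

from dataclasses import replace

import numpy as np
import pytest

from oakbiomass import (correlate_proportions_climate, proportions,
                        summarize_by_class)
from oakbiomass.data import CLIMATE_KEYS, TreeRecord
from oakbiomass.synthetic import DEFAULT_CLIMATE_RANGES


def _tree(dbh=10.0, height=8.0, age=40.0, stem=50.0, branch=20.0, leaf=5.0,
          root=25.0, climate=None, tid="t"):
    return TreeRecord(tree_id=tid, dbh=dbh, height=height, age=age, stem=stem,
                      branch=branch, leaf=leaf, root=root,
                      climate=climate or {})


class TestProportions:
    def test_hand_computed_fractions(self):
        p = proportions(_tree())
        assert p == {"stem": 0.50, "branch": 0.20, "leaf": 0.05, "root": 0.25}

    def test_equal_components_split_evenly(self):
        p = proportions(_tree(stem=3, branch=3, leaf=3, root=3))
        assert all(v == pytest.approx(0.25) for v in p.values())

    def test_stem_only_tree(self):
        p = proportions(_tree(stem=10, branch=0, leaf=0, root=0))
        assert p["stem"] == 1.0 and p["branch"] == 0.0

    def test_missing_root_is_an_error(self):
        with pytest.raises(ValueError):
            proportions(_tree(root=None))

    def test_fractions_sum_to_one(self, default_population):
        for r in default_population:
            if r.has_root:
                assert sum(proportions(r).values()) == pytest.approx(1.0,
                                                                     abs=1e-12)


class TestClassSummaries:
    def test_one_tree_per_bin_reproduces_that_tree(self):
        recs = [_tree(dbh=d, tid=str(d)) for d in (2, 6, 16, 32)]
        summ = summarize_by_class(recs, "diameter")
        assert summ.counts.sum() == 4
        filled = summ.mean_proportions.dropna()
        assert np.allclose(filled["stem"], 0.50)

    def test_diameter_binning_uses_nearest_center(self):
        recs = [_tree(dbh=9.9, tid="a"), _tree(dbh=10.1, tid="b")]
        summ = summarize_by_class(recs, "diameter")
        # midpoint between the 8 and 12 cm classes is 10
        assert summ.counts[3] == 1 and summ.counts[4] == 1

    def test_age_bins_follow_study_groups(self):
        recs = [_tree(age=a, tid=str(a)) for a in (5, 14.9, 15, 89.9, 105, 130)]
        summ = summarize_by_class(recs, "age")
        assert summ.bins[0] == (5, 15) and summ.bins[-1] == (105, 130)
        assert summ.counts[0] == 2          # 5 and 14.9
        assert summ.counts[-1] == 2         # 105 and 130 (final bin closed)

    def test_empty_bins_flagged(self):
        recs = [_tree(dbh=2.0)]
        with pytest.warns(UserWarning, match="empty"):
            summ = summarize_by_class(recs, "diameter")
        assert np.isnan(summ.mean_proportions.iloc[5]["stem"])

    def test_bin_means_bounded_by_member_range(self, default_population):
        summ = summarize_by_class(default_population, "diameter")
        rooted = [r for r in default_population if r.has_root]
        props = [proportions(r)["root"] for r in rooted]
        assert np.nanmin(summ.mean_proportions["root"]) >= min(props) - 1e-12
        assert np.nanmax(summ.mean_proportions["root"]) <= max(props) + 1e-12

    def test_declining_root_share_shows_monotone_trend(self,
                                                       default_population):
        """The generator's ratio-form root (negative DBH exponent) yields
        root proportions that decline across diameter classes."""
        summ = summarize_by_class(default_population, "diameter")
        col = summ.mean_proportions["root"].dropna().to_numpy()
        # allow sampling noise: overall downward trend across classes
        assert col[0] > col[-1]
        assert np.polyfit(np.arange(col.size), col, 1)[0] < 0


class TestClimateCorrelations:
    def _population(self, seed, n=53, link=None):
        rng = np.random.default_rng(seed)
        recs = []
        for i in range(n):
            climate = {k: float(rng.uniform(*DEFAULT_CLIMATE_RANGES[k]))
                       for k in CLIMATE_KEYS}
            stem = 50 + rng.normal(0, 5)
            branch = 20 + rng.normal(0, 3)
            if link == "affine":
                branch = 5.0 + 0.1 * climate["PAS"]
            elif link == "anti":
                branch = 60.0 - 0.1 * climate["PAS"]
            recs.append(_tree(stem=float(stem), branch=float(branch),
                              leaf=float(5 + rng.normal(0, 1)),
                              root=25.0, climate=climate, tid=str(i)))
        return recs

    def test_affine_link_gives_extreme_correlation(self):
        table = correlate_proportions_climate(self._population(1, link="affine"))
        row = table[(table.climate == "PAS") & (table.component == "branch")]
        assert float(row.r.iloc[0]) > 0.9
        table = correlate_proportions_climate(self._population(2, link="anti"))
        row = table[(table.climate == "PAS") & (table.component == "branch")]
        assert float(row.r.iloc[0]) < -0.9

    def test_type_one_error_rate_near_alpha(self):
        """Independent climate: ~5% of pairs flagged at alpha=0.05."""
        flagged = total = 0
        for rep in range(300):
            table = correlate_proportions_climate(self._population(100 + rep))
            flagged += int(table.significant.sum())
            total += len(table)
        rate = flagged / total
        assert 0.03 < rate < 0.07

    def test_holm_adjustment_is_more_conservative(self):
        recs = self._population(7)
        raw = correlate_proportions_climate(recs)
        holm = correlate_proportions_climate(recs, holm=True)
        assert holm.significant.sum() <= raw.significant.sum()

    def test_zero_variance_pair_reported_missing(self):
        recs = self._population(8)
        flat = dict(recs[0].climate)
        flat["EXT"] = 35.0
        recs = [replace(r, climate={**r.climate, "EXT": 35.0}) for r in recs]
        with pytest.warns(UserWarning, match="zero variance"):
            table = correlate_proportions_climate(recs)
        row = table[(table.climate == "EXT") & (table.component == "stem")]
        assert np.isnan(row.r.iloc[0])
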