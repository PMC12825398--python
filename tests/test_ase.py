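"""Discriminant-allele transformation and per-gene maternal proportions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import imprintome as im
from imprintome.ase import gene_maternal_proportion, site_parental_counts
from imprintome.simdata import expected_alt_frequency
from imprintome.sites import SiteCategory


def pooled_transmission_expected_frequency(theta: float, het_parent: str) -> float:
    """Enumeration oracle for the het-parent private-allele pooled frequency.

    Pooled seeds split evenly over the two transmission states of the
    heterozygous parent; in the transmitting state the private allele
    appears in all of that parent's reads, in the other state never, and
    the homozygous parent never contributes it.
    """
    share = theta if het_parent == "mother" else 1.0 - theta
    states = [(0.5, share), (0.5, 0.0)]  # (state probability, private-allele freq)
    return sum(p * f for p, f in states)


class TestSiteParentalCounts:
    def test_reciprocal_hom_direct_assignment(self):
        s = site_parental_counts(60, 40, SiteCategory.RECIPROCAL_HOM, (0, 0), (1, 1))
        assert (s.m_hat, s.p_hat, s.truncated) == (60.0, 40.0, False)

    def test_mother_het_doubles_private_allele(self):
        # mother 0/1, father 0/0: private allele is ALT, seen 10 of 100
        s = site_parental_counts(90, 10, SiteCategory.MOTHER_HET, (0, 1), (0, 0))
        assert (s.m_hat, s.p_hat) == (20.0, 80.0)
        assert s.m_hat / s.total == pytest.approx(0.2)

    def test_father_het_doubles_private_allele(self):
        # father 0/1, mother 0/0: private allele is ALT, seen 30 of 100
        s = site_parental_counts(70, 30, SiteCategory.FATHER_HET, (0, 0), (0, 1))
        assert (s.m_hat, s.p_hat) == (40.0, 60.0)

    def test_doubling_caps_at_site_total(self):
        s = site_parental_counts(40, 60, SiteCategory.MOTHER_HET, (0, 1), (0, 0))
        assert (s.m_hat, s.p_hat, s.truncated) == (100.0, 0.0, True)

    def test_uninformative_or_empty_site_rejected(self):
        with pytest.raises(im.ContractError):
            site_parental_counts(10, 10, SiteCategory.UNINFORMATIVE, (0, 1), (0, 1))
        with pytest.raises(im.ContractError):
            site_parental_counts(0, 0, SiteCategory.RECIPROCAL_HOM, (0, 0), (1, 1))

    @given(
        count_ref=st.integers(0, 500),
        count_alt=st.integers(0, 500),
        category=st.sampled_from(
            [SiteCategory.RECIPROCAL_HOM, SiteCategory.MOTHER_HET,
             SiteCategory.FATHER_HET]
        ),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_transformation_conserves_reads_and_bounds_theta(
        self, count_ref, count_alt, category
    ):
        if count_ref + count_alt == 0:
            return
        gts = {
            SiteCategory.RECIPROCAL_HOM: ((0, 0), (1, 1)),
            SiteCategory.MOTHER_HET: ((0, 1), (0, 0)),
            SiteCategory.FATHER_HET: ((0, 0), (0, 1)),
        }[category]
        s = site_parental_counts(count_ref, count_alt, category, *gts)
        assert s.m_hat >= 0 and s.p_hat >= 0
        assert s.m_hat + s.p_hat == count_ref + count_alt
        assert 0.0 <= s.m_hat / s.total <= 1.0


class TestTransmissionModel:
    @pytest.mark.parametrize("theta", [0.1, 0.5, 0.8, 0.95])
    @pytest.mark.parametrize("het_parent", ["mother", "father"])
    def test_expected_private_allele_frequency_is_half_share(self, theta, het_parent):
        oracle = pooled_transmission_expected_frequency(theta, het_parent)
        if het_parent == "mother":  # mother 0/1, father 0/0 -> alt is private
            model = expected_alt_frequency(theta, 1, 0, rho_c=0.0)
            assert model == pytest.approx(theta / 2)
        else:  # father 0/1, mother 0/0
            model = expected_alt_frequency(theta, 0, 1, rho_c=0.0)
            assert model == pytest.approx((1 - theta) / 2)
        assert model == pytest.approx(oracle)

    def test_mixed_category_estimator_matches_hom_only(self, rng):
        """Doubling het-site private-allele counts makes a gene estimated
        from all three categories agree with the reciprocal-hom-only
        estimator within Monte-Carlo error."""
        theta, depth, n_each = 0.6, 300, 400
        hom_alt = rng.binomial(depth, theta, n_each)  # mother 1/1, father 0/0
        mhet_alt = rng.binomial(depth, theta / 2, n_each)  # mother 0/1, father 0/0
        fhet_alt = rng.binomial(depth, (1 - theta) / 2, n_each)  # father 0/1
        hom = [
            site_parental_counts(depth - a, a, SiteCategory.RECIPROCAL_HOM, (1, 1), (0, 0))
            for a in hom_alt
        ]
        het = [
            site_parental_counts(depth - a, a, SiteCategory.MOTHER_HET, (0, 1), (0, 0))
            for a in mhet_alt
        ] + [
            site_parental_counts(depth - a, a, SiteCategory.FATHER_HET, (0, 0), (0, 1))
            for a in fhet_alt
        ]
        theta_hom = gene_maternal_proportion(hom, gene_id="g").theta
        theta_mixed = gene_maternal_proportion(hom + het, gene_id="g").theta
        assert theta_hom == pytest.approx(theta, abs=0.01)
        assert theta_mixed == pytest.approx(theta_hom, abs=0.01)

    def test_estimator_consistency_at_extreme_depth(self, rng):
        """theta-hat converges to the true theta as depth grows."""
        theta, depth = 0.7, 10_000
        alt = rng.binomial(depth, theta, 20)
        ases = [
            site_parental_counts(depth - a, a, SiteCategory.RECIPROCAL_HOM, (1, 1), (0, 0))
            for a in alt
        ]
        assert gene_maternal_proportion(ases, gene_id="g").theta == pytest.approx(
            theta, abs=0.01
        )


class TestGeneMaternalProportion:
    def test_depth_weighted_aggregation(self):
        # mother 1/1: maternal reads are the ALT counts (10, then 30)
        ases = [
            site_parental_counts(10, 10, SiteCategory.RECIPROCAL_HOM, (1, 1), (0, 0)),
            site_parental_counts(10, 30, SiteCategory.RECIPROCAL_HOM, (1, 1), (0, 0)),
        ]
        g = gene_maternal_proportion(ases, gene_id="g")
        assert (g.M, g.P) == (40.0, 20.0)
        assert g.theta == pytest.approx(2 / 3, abs=1e-4)

    def test_zero_maternal_reads_boundary(self):
        g = gene_maternal_proportion(
            [site_parental_counts(25, 0, SiteCategory.RECIPROCAL_HOM, (1, 1), (0, 0))],
            gene_id="g",
        )
        assert g.theta == 0.0

    def test_below_min_reads_is_insufficient(self):
        g = gene_maternal_proportion(
            [site_parental_counts(5, 3, SiteCategory.RECIPROCAL_HOM, (0, 0), (1, 1))],
            min_reads=10, gene_id="g",
        )
        assert g.status == "insufficient" and g.theta is None

    def test_empty_input_is_error(self):
        with pytest.raises(im.ContractError):
            gene_maternal_proportion([], gene_id="g")


class TestDatasetMean:
    def frame(self, thetas, direction="1x2"):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(thetas))],
                "direction_id": direction,
                "M": 10, "P": 10, "theta": thetas, "n_sites": 1,
                "n_reads": 20, "status": "ok",
            }
        )

    def designs(self):
        return [
            im.CrossDesign("1x2", "plant1", "plant2", ("a",)),
            im.CrossDesign("2x1", "plant2", "plant1", ("b",)),
        ]

    def test_unweighted_mean(self):
        df = self.frame([0.4, 0.5, 0.6])
        assert im.dataset_mean_maternal_proportion(df, "plant1", self.designs()) == 0.5

    def test_all_maternal_boundary(self):
        df = self.frame([1.0, 1.0])
        assert im.dataset_mean_maternal_proportion(df, "plant1", self.designs()) == 1.0

    def test_no_eligible_genes_is_error(self):
        df = self.frame([0.5])
        with pytest.raises(im.ContractError):
            im.dataset_mean_maternal_proportion(df, "plant2", self.designs())


def test_parent_role_relabeling_flips_theta_exactly(small_dataset):
    """Swapping mother/father roles in both directions maps every gene's
    theta to 1 - theta exactly, truncated het sites included."""
    d = small_dataset
    merged = im.merge_replicate_counts(d["counts"], d["designs"])
    ase = im.build_gene_ase_table(d["sites"], merged, d["designs"])
    swapped_designs = [
        im.CrossDesign(x.direction_id, x.father_plant_id, x.mother_plant_id,
                       x.replicate_library_ids)
        for x in d["designs"]
    ]
    ase_sw = im.build_gene_ase_table(d["sites"], merged, swapped_designs)
    j = ase.merge(ase_sw, on=["gene_id", "direction_id"], suffixes=("", "_sw"))
    ok = j["status"].eq("ok") & j["status_sw"].eq("ok")
    assert ok.any()
    # exact up to one ulp of the final division
    assert np.allclose(j.loc[ok, "theta_sw"], 1.0 - j.loc[ok, "theta"],
                       atol=1e-12, rtol=0)
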