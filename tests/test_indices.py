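"""Ecosystem indices, trophic levels, Box-Cox standardisation and the
composite SSE score."""

import numpy as np
import pytest
from scipy import stats

from isolim.indices import (INDEX_NAMES, boxcox_standardize, composite_sse,
                            compute_indices, fit_standardizers,
                            trophic_levels)


def _flows(model, **kw):
    x = np.zeros(model.n_flows)
    for key, v in kw.items():
        src, dst = key.split("__")
        x[model.flow_id(src, dst)] = v
    return x


class TestTrophicLevels:
    def test_pure_herbivore_is_level_two(self, model):
        x = _flows(model, DTM__MES=1.0, CYA__HNF=1.0, CYA__MIC=1.0)
        assert trophic_levels(x, model)["MES"] == pytest.approx(2.0)

    def test_mixed_diet_hand_arithmetic(self, model):
        # MES: 50% DTM (TL 1), 50% MIC; MIC eats only CYA -> TL 2
        x = _flows(model, DTM__MES=0.5, MIC__MES=0.5, CYA__MIC=1.0,
                   CYA__HNF=1.0)
        assert trophic_levels(x, model)["MES"] == pytest.approx(2.5)

    def test_self_loop_fixed_point(self, model):
        # self-loop fraction s, rest of diet at TL 1: TL = (2 - s)/(1 - s)
        s = 0.2
        x = _flows(model, MES__MES=s, DTM__MES=1 - s, CYA__HNF=1.0,
                   CYA__MIC=1.0)
        assert trophic_levels(x, model)["MES"] == pytest.approx(2.25)

    def test_consumer_of_level_one_prey_is_exactly_two(self, model):
        rng = np.random.default_rng(0)
        a, b, c = rng.random(3) + 0.1
        x = _flows(model, CYA__MIC=a, DTM__MIC=b, DET__MIC=c, CYA__HNF=1.0,
                   DTM__MES=1.0)
        assert trophic_levels(x, model)["MIC"] == pytest.approx(2.0)

    def test_zero_ingestion_raises(self, model):
        x = _flows(model, DTM__MES=1.0, CYA__MIC=1.0)  # HNF eats nothing
        with pytest.raises(ValueError, match="HNF"):
            trophic_levels(x, model)


class TestComputeIndices:
    def _base_flows(self, model):
        return _flows(model, NO3__CYA=0.3, NO3__DTM=0.4, NH4__CYA=0.1,
                      NH4__DTM=0.1, CYA__DOM=0.05, DTM__DOM=0.05,
                      CYA__HNF=0.2, CYA__MIC=0.1, DTM__MIC=0.1, DTM__MES=0.3,
                      HNF__MIC=0.05, HNF__MES=0.05, MIC__MES=0.1,
                      DET__HNF=0.02, DET__MIC=0.02, DET__MES=0.02,
                      HNF__NH4=0.03, MIC__NH4=0.03, MES__NH4=0.05,
                      HNF__DOM=0.02, MIC__DOM=0.02, MES__DOM=0.05,
                      HNF__DET=0.02, MIC__DET=0.02, MES__DET=0.05,
                      DOM__NH4=0.2, MES__HTL=0.1)

    def test_no_fixation_flows_give_zero_index(self, model):
        idx = compute_indices(self._base_flows(model), model)
        assert idx.n2_fixation == 0.0
        assert idx.total_n_uptake == pytest.approx(0.9)

    def test_mesohaline_truth_fraction_rounds_to_ten_percent(self, mesohaline):
        """The diazotroph-scenario truth column: fixation 0.10048 of total
        uptake 0.96 is 10.5%, printing as 10%."""
        frac = 100 * mesohaline.truth["n2_fixation"] / mesohaline.truth["total_n_uptake"]
        assert round(frac) == 10

    def test_lossless_grazers_have_unit_gge(self, model):
        x = _flows(model, NO3__CYA=1.0, CYA__HNF=0.5, CYA__MIC=0.5,
                   DTM__MES=0.2, NO3__DTM=0.4, HNF__MES=0.2, MIC__MES=0.2,
                   MES__HTL=0.3)
        idx = compute_indices(x, model)
        assert idx.protozoan_gge == pytest.approx(1.0)
        assert idx.mes_gge == pytest.approx(1.0)

    def test_zero_npp_rejected(self, model):
        with pytest.raises(ValueError, match="primary production"):
            compute_indices(np.zeros(model.n_flows), model)

    def test_chain_fractions_bounded_by_grazing(self, model):
        x = self._base_flows(model)
        idx = compute_indices(x, model)
        npp = idx.cya_npp + idx.dtm_npp
        total_grazing = (idx.protozoan_grazing
                         + x[model.flow_id("DTM", "MES")]
                         + x[model.flow_id("HNF", "MES")]
                         + x[model.flow_id("MIC", "MES")])
        assert idx.herbivorous_chain + idx.multivorous_chain <= \
            total_grazing / npp + 1e-12


class TestBoxCox:
    def test_lognormal_skew_reduced(self):
        rng = np.random.default_rng(0)
        y = np.exp(rng.standard_normal(400))
        _, z = boxcox_standardize(y)
        assert abs(stats.skew(z)) < abs(stats.skew(y))
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std() == pytest.approx(1.0, abs=1e-9)

    def test_normal_pool_standardised(self):
        rng = np.random.default_rng(1)
        y = rng.normal(10.0, 2.0, size=300)
        params, z = boxcox_standardize(y)
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std() == pytest.approx(1.0, abs=1e-9)

    def test_negative_values_shifted_not_rejected(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0.0, 1.0, size=200) - 5.0
        params, z = boxcox_standardize(y)
        assert np.all(np.isfinite(z))
        assert y.min() + params.lambda2 > 0

    def test_constant_pool_rejected(self):
        with pytest.raises(ValueError):
            boxcox_standardize(np.full(10, 3.0))


class TestCompositeSSE:
    def _setup(self):
        rng = np.random.default_rng(3)
        true = {k: float(v) for k, v in zip(INDEX_NAMES,
                                            rng.random(15) + 0.5)}
        pools = {k: np.concatenate([[true[k]], true[k] * (0.5 + rng.random(8))])
                 for k in INDEX_NAMES}
        return true, fit_standardizers(pools)

    def test_perfect_prediction_scores_zero(self):
        true, std = self._setup()
        assert composite_sse(dict(true), true, std) == pytest.approx(0.0)

    def test_one_standardised_unit_off_scores_one(self):
        true, std = self._setup()
        name = INDEX_NAMES[0]
        bc = std[name]
        pred = dict(true)
        # move the first index by exactly one standardised unit
        z_target = bc.transform(true[name]) + 1.0
        raw = z_target * bc.sd + bc.mean
        if abs(bc.lambda1) < 1e-9:
            val = np.exp(raw * bc.scale) - bc.lambda2
        else:
            val = (raw * bc.lambda1 * bc.scale + 1.0) ** (1.0 / bc.lambda1) \
                - bc.lambda2
        pred[name] = float(val)
        assert composite_sse(pred, true, std) == pytest.approx(1.0, abs=1e-6)

    def test_permutation_invariant_and_nonnegative(self):
        true, std = self._setup()
        rng = np.random.default_rng(4)
        pred = {k: v * (1 + 0.1 * rng.standard_normal()) for k, v in true.items()}
        s1 = composite_sse(pred, true, std)
        shuffled = dict(reversed(list(pred.items())))
        assert composite_sse(shuffled, true, std) == pytest.approx(s1)
        assert s1 >= 0

    def test_missing_index_rejected(self):
        true, std = self._setup()
        pred = dict(true)
        pred.pop(INDEX_NAMES[3])
        with pytest.raises(KeyError):
            composite_sse(pred, true, std)
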