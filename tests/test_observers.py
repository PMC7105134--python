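"""Unit tests for the simulated-observer models."""

import numpy as np
import pytest

from petseg import (
    ObserverProfile,
    Strategy,
    default_panel,
    ideal_pct,
    jaccard,
    simulate_cell,
    simulate_manual,
    simulate_select_best,
    threshold_pct_max,
)
from petseg.observers import Experience, cell_seed, run_study
from petseg.segment import PANEL_LABELS, run_auto_panel


def _observer(**kw):
    base = dict(
        id="obs",
        experience=Experience.EXPERIENCED,
        bias_pct=0.0,
        sd_pct={Strategy.MANUAL: 0.0, Strategy.THRESHOLD: 0.0, Strategy.GRADIENT: 0.0},
        manual_edit_rate=0.0,
        select_accuracy_p=1.0,
    )
    base.update(kw)
    return ObserverProfile(**base)


class TestProfile:
    def test_sd_ordering_enforced(self):
        with pytest.raises(ValueError, match="sd_gradient"):
            ObserverProfile(
                id="x",
                sd_pct={Strategy.MANUAL: 1.0, Strategy.THRESHOLD: 2.0, Strategy.GRADIENT: 3.0},
            )

    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            _observer(select_accuracy_p=1.5)
        with pytest.raises(ValueError):
            _observer(manual_edit_rate=1.0)

    def test_default_panel_composition(self):
        panel = default_panel()
        assert len(panel) == 6
        exp = [o for o in panel if o.experience is Experience.EXPERIENCED]
        nov = [o for o in panel if o.experience is Experience.NOVICE]
        assert len(exp) == 3 and len(nov) == 3
        assert len({o.id for o in panel}) == 6
        for o in panel:
            assert o.sd_pct[Strategy.GRADIENT] <= o.sd_pct[Strategy.THRESHOLD]


class TestIdealPct:
    def test_matches_grid_search_oracle(self, small_case):
        fast = ideal_pct(small_case, grid_step=1.0)
        best_pct, best_jc = None, -1.0
        for pct in range(0, 101):
            mask = threshold_pct_max(small_case.image, small_case.rough_mask, pct).mask
            if not (mask.values.any() or small_case.ground_truth.values.any()):
                continue
            try:
                jc = jaccard(mask, small_case.ground_truth)
            except ValueError:
                jc = -1.0
            if jc > best_jc:
                best_jc, best_pct = jc, pct
        assert fast == best_pct

    def test_gives_good_overlap(self, small_case):
        pct = ideal_pct(small_case)
        mask = threshold_pct_max(small_case.image, small_case.rough_mask, pct).mask
        assert jaccard(mask, small_case.ground_truth) > 0.7


class TestInteractive:
    def test_degenerate_observer_is_ideal(self, small_case):
        obs = _observer()
        rec = simulate_cell(obs, small_case, Strategy.THRESHOLD, global_seed=0)
        ideal = ideal_pct(small_case)
        assert rec.provenance["pct"] == np.round(ideal)
        expected = threshold_pct_max(small_case.image, small_case.rough_mask, np.round(ideal))
        np.testing.assert_array_equal(rec.mask.values, expected.mask.values)

    def test_chosen_pct_is_integer_and_clipped(self, small_case):
        obs = _observer(
            bias_pct=5.0,
            sd_pct={Strategy.MANUAL: 30.0, Strategy.THRESHOLD: 30.0, Strategy.GRADIENT: 30.0},
        )
        for seed in range(20):
            rec = simulate_cell(obs, small_case, Strategy.GRADIENT, global_seed=seed)
            pct = rec.provenance["pct"]
            assert pct == int(pct) and 0.0 <= pct <= 100.0

    def test_gradient_spread_tighter_than_threshold(self, small_case):
        obs = _observer(
            sd_pct={Strategy.MANUAL: 10.0, Strategy.THRESHOLD: 8.0, Strategy.GRADIENT: 0.5}
        )
        t_pcts, g_pcts = [], []
        for seed in range(40):
            t_pcts.append(
                simulate_cell(obs, small_case, Strategy.THRESHOLD, seed).provenance["pct"]
            )
            g_pcts.append(simulate_cell(obs, small_case, Strategy.GRADIENT, seed).provenance["pct"])
        assert np.std(g_pcts) < np.std(t_pcts)

    def test_rejects_select_best(self, small_case):
        from petseg.observers import simulate_interactive

        with pytest.raises(ValueError):
            simulate_interactive(
                _observer(), small_case, Strategy.SELECT_BEST, np.random.default_rng(0)
            )


class TestManual:
    def test_no_edits_equals_interactive(self, small_case):
        obs = _observer()
        rec = simulate_manual(obs, small_case, np.random.default_rng(0))
        base = threshold_pct_max(
            small_case.image, small_case.rough_mask, rec.provenance["pct"]
        ).mask
        np.testing.assert_array_equal(rec.mask.values, base.values)
        assert rec.provenance["n_added"] == rec.provenance["n_removed"] == 0

    def test_edits_touch_only_boundary(self, small_case):
        from scipy import ndimage

        obs = _observer(manual_edit_rate=0.3)
        rec = simulate_manual(obs, small_case, np.random.default_rng(5))
        base = threshold_pct_max(
            small_case.image, small_case.rough_mask, rec.provenance["pct"]
        ).mask.values
        edited = rec.mask.values
        changed = base ^ edited
        struct = ndimage.generate_binary_structure(3, 1)
        inner = base & ~ndimage.binary_erosion(base, structure=struct)
        outer = ndimage.binary_dilation(base, structure=struct) & ~base
        assert np.all(changed <= (inner | outer))
        # the deep interior of the pre-edit mask is untouched
        interior = ndimage.binary_erosion(base, structure=struct)
        assert np.all(edited[interior])

    def test_experienced_edits_stay_in_rough(self, small_case):
        obs = _observer(manual_edit_rate=0.3)
        rec = simulate_manual(obs, small_case, np.random.default_rng(7))
        assert not np.any(rec.mask.values & ~small_case.rough_mask.values)

    def test_novice_may_annex_confounder_voxels(self, confounder_case):
        outside = ~confounder_case.rough_mask.values
        nov = _observer(experience=Experience.NOVICE, manual_edit_rate=0.3)
        exp = _observer(manual_edit_rate=0.3)
        nov_out = exp_out = 0
        for seed in range(20):
            nov_out += int(
                (simulate_manual(nov, confounder_case, np.random.default_rng(seed)).mask.values
                 & outside).sum()
            )
            exp_out += int(
                (simulate_manual(exp, confounder_case, np.random.default_rng(seed)).mask.values
                 & outside).sum()
            )
        assert nov_out > 0  # novices sometimes annex adjacent organ voxels
        assert exp_out == 0  # experienced edits never leave the rough mask

    def test_edit_counts_scale_with_rate(self, small_case):
        totals = []
        for rate in (0.02, 0.3):
            obs = _observer(manual_edit_rate=rate)
            n = 0
            for seed in range(10):
                rec = simulate_manual(obs, small_case, np.random.default_rng(seed))
                n += rec.provenance["n_added"] + rec.provenance["n_removed"]
            totals.append(n)
        assert totals[1] > totals[0] > 0


class TestSelectBest:
    def test_perfect_accuracy_picks_best(self, small_case):
        panel = run_auto_panel(small_case.image, small_case.rough_mask)
        jcs = {lb: jaccard(panel[lb].mask, small_case.ground_truth) for lb in PANEL_LABELS}
        best = max(PANEL_LABELS, key=lambda lb: jcs[lb])
        for seed in range(5):
            rec = simulate_select_best(
                _observer(select_accuracy_p=1.0), small_case, np.random.default_rng(seed),
                panel=panel,
            )
            assert rec.provenance["chosen"] == best == rec.provenance["best"]

    def test_zero_accuracy_never_picks_best(self, small_case):
        panel = run_auto_panel(small_case.image, small_case.rough_mask)
        seen = set()
        for seed in range(60):
            rec = simulate_select_best(
                _observer(select_accuracy_p=0.0), small_case, np.random.default_rng(seed),
                panel=panel,
            )
            assert rec.provenance["chosen"] != rec.provenance["best"]
            seen.add(rec.provenance["chosen"])
        # errors spread over all three non-best members
        assert len(seen) == 3

    def test_mask_matches_chosen_member(self, small_case):
        panel = run_auto_panel(small_case.image, small_case.rough_mask)
        rec = simulate_select_best(
            _observer(select_accuracy_p=0.5), small_case, np.random.default_rng(3), panel=panel
        )
        np.testing.assert_array_equal(
            rec.mask.values, panel[rec.provenance["chosen"]].mask.values
        )


class TestSeeding:
    def test_cell_seed_depends_on_all_parts(self):
        base = cell_seed("L00", "obs1", Strategy.MANUAL, 0)
        assert base != cell_seed("L01", "obs1", Strategy.MANUAL, 0)
        assert base != cell_seed("L00", "obs2", Strategy.MANUAL, 0)
        assert base != cell_seed("L00", "obs1", Strategy.GRADIENT, 0)
        assert base != cell_seed("L00", "obs1", Strategy.MANUAL, 1)
        assert 0 <= base < 2**31

    def test_simulate_cell_reproducible(self, small_case):
        panel = default_panel()
        a = simulate_cell(panel[1], small_case, Strategy.MANUAL, global_seed=4)
        b = simulate_cell(panel[1], small_case, Strategy.MANUAL, global_seed=4)
        np.testing.assert_array_equal(a.mask.values, b.mask.values)


class TestRunStudy:
    def test_factorial_coverage(self, small_case, clean_case):
        observers = [_observer(id="a"), _observer(id="b")]
        records = run_study([small_case, clean_case], observers, seed=0)
        assert len(records) == 2 * 2 * 4
        keys = {(r.lesion_id, r.observer_id, r.strategy) for r in records}
        assert len(keys) == len(records)

    def test_validation(self, small_case):
        with pytest.raises(ValueError):
            run_study([], [_observer(id="a"), _observer(id="b")])
        with pytest.raises(ValueError):
            run_study([small_case], [_observer(id="a")])
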