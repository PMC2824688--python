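"""Stochastic engine: degenerate traces, conservation, determinism and
agreement with a binomial oracle."""

import numpy as np
import pytest

import carpsim as cs
from carpsim.states import EventType, HistoryState
from conftest import uniform_table

ADM = EventType.CHD_ADMISSION_NO_CARP


def person(age=50, sex="male", state=HistoryState.NO_HISTORY, pid="p"):
    return cs.Person(pid, sex, age, state)


def one_person_cohort(**kw):
    return cs.BaselineCohort.from_persons([person(**kw)])


class TestSimulatePersonYear:
    def test_null_risks_change_nothing_but_age(self):
        t = uniform_table(2001, 2001)
        p = person(age=50)
        out = cs.simulate_person_year(p, 2001, t, np.random.default_rng(0))
        assert out.events == [] and not out.died and not out.aged_out
        assert p.age == 51 and p.state == HistoryState.NO_HISTORY

    def test_certain_non_chd_death(self):
        t = uniform_table(2001, 2001, risks_by_event=[0, 0, 0, 0, 1.0])
        p = person()
        out = cs.simulate_person_year(p, 2001, t, np.random.default_rng(0))
        assert out.events == [EventType.NON_CHD_DEATH]
        assert out.died and not p.alive

    def test_death_draw_is_last_event_and_terminal(self):
        t = uniform_table(2001, 2001, risks_by_event=[0, 0, 0, 1.0, 0])
        p = person(state=HistoryState.CABG_HISTORY)
        out = cs.simulate_person_year(p, 2001, t, np.random.default_rng(1))
        assert out.events == [EventType.CHD_DEATH]
        assert out.end_state == HistoryState.CABG_HISTORY

    def test_pci_then_follow_on_cabg_uses_updated_state_risks(self):
        """First-draw PCI moves the person to PCI-no-CABG; a certain CABG
        at that state's risks is drawn next, ending at CABG history."""
        t = uniform_table(2001, 2001)
        # NO_HISTORY: PCI certain; PCI_NO_CABG: CABG certain
        t.values[:, :, :, int(HistoryState.NO_HISTORY), :] = [0, 0, 1.0, 0, 0]
        t.values[:, :, :, int(HistoryState.PCI_NO_CABG), :] = [0, 1.0, 0, 0, 0]
        p = person()
        out = cs.simulate_person_year(p, 2001, t, np.random.default_rng(0))
        assert out.events == [EventType.PCI, EventType.CABG]
        assert out.end_state == HistoryState.CABG_HISTORY

    def test_admission_permits_two_follow_on_carps(self):
        t = uniform_table(2001, 2001)
        t.values[:, :, :, int(HistoryState.NO_HISTORY), :] = [1.0, 0, 0, 0, 0]
        t.values[:, :, :, int(HistoryState.CHD_NO_CARP), :] = [0, 0, 1.0, 0, 0]
        t.values[:, :, :, int(HistoryState.PCI_NO_CABG), :] = [0, 0, 1.0, 0, 0]
        p = person()
        out = cs.simulate_person_year(p, 2001, t, np.random.default_rng(0))
        # admission, then two PCIs (the two-CARP cap ends the year)
        assert out.events == [ADM, EventType.PCI, EventType.PCI]
        assert out.end_state == HistoryState.PCI_NO_CABG

    def test_cap_of_three_events_per_year(self):
        t = uniform_table(2001, 2001, risks_by_event=[1.0, 0, 0, 0, 0])
        t.values[..., int(EventType.CABG)] = 0.0
        t.values[:, :, :, 1:, int(EventType.PCI)] = 1.0
        t.values[:, :, :, 1:, int(ADM)] = 0.0
        p = person()
        out = cs.simulate_person_year(p, 2001, t, np.random.default_rng(0))
        assert len(out.events) == 3

    def test_pci_does_not_demote_cabg_history(self):
        t = uniform_table(2001, 2001, risks_by_event=[0, 0, 1.0, 0, 0])
        t.values[..., int(EventType.PCI)] = 1.0
        t.values[:, :, :, :, [0, 1, 3, 4]] = 0.0
        p = person(state=HistoryState.CABG_HISTORY)
        out = cs.simulate_person_year(p, 2001, t, np.random.default_rng(0))
        assert out.end_state == HistoryState.CABG_HISTORY

    def test_missing_cell_aborts(self):
        t = cs.AnnualRiskTable(2001, 2001)  # empty
        with pytest.raises(cs.IncompleteTableError):
            cs.simulate_person_year(person(), 2001, t, np.random.default_rng(0))


class TestSimulateCohort:
    def test_zero_risks_all_alive(self):
        cfg = cs.SyntheticConfig(n_persons=100, seed=4)
        cohort = cs.generate_cohort(cfg)
        t = uniform_table(2001, 2010)
        rep = cs.simulate_cohort(cohort, t, 2001, 2010, np.random.default_rng(0))
        assert rep.counts.sum() == 0
        assert rep.n_died == 0
        # only age-outs remove people when risks are zero
        assert rep.n_alive + rep.n_aged_out == 100

    def test_79_year_old_simulated_once_then_aged_out(self):
        cohort = one_person_cohort(age=79)
        t = uniform_table(2001, 2010, risks_by_event=[0, 0, 0.5, 0, 0])
        t.values[:, :, :, 1:, :] = 0.0  # no follow-on or later-state events
        reps = [cs.simulate_cohort(cohort, t, 2001, 2010, np.random.default_rng(s))
                for s in range(200)]
        # events can only ever fall in the first year
        for rep in reps:
            assert rep.counts[1:].sum() == 0
            assert rep.n_aged_out == 1
        frac = np.mean([r.counts[0, int(EventType.PCI)] for r in reps])
        assert frac == pytest.approx(0.5, abs=0.15)

    def test_certain_chd_death_absorbs_in_first_year(self):
        cohort = one_person_cohort(age=40)
        t = uniform_table(2001, 2010, risks_by_event=[0, 0, 0, 1.0, 0])
        rep = cs.simulate_cohort(cohort, t, 2001, 2010, np.random.default_rng(3))
        assert rep.counts[0, int(EventType.CHD_DEATH)] == 1
        assert rep.counts.sum() == 1
        assert rep.n_died == 1

    def test_conservation_every_replicate(self, small_fitted_results):
        res = small_fitted_results
        sim = res.simulate(n_replicates=20, master_seed=5)
        n = len(res.model.cohort)
        assert (sim.end_status.sum(axis=1) == n).all()

    def test_state_monotonicity(self):
        """States never move down the dominance order."""
        cfg = cs.SyntheticConfig(n_persons=50, seed=6)
        cohort = cs.generate_cohort(cfg)
        # exaggerated risks so transitions actually happen
        t = uniform_table(2001, 2010, risks_by_event=[0.2, 0.1, 0.1, 0.02, 0.02])
        rng = np.random.default_rng(2)
        for p in cohort.persons():
            prev = int(p.state)
            for year in range(2001, 2011):
                if not p.alive or p.aged_out:
                    break
                cs.simulate_person_year(p, year, t, rng)
                assert int(p.state) >= prev
                prev = int(p.state)


class TestRunReplicates:
    def test_determinism_same_seed(self, small_fitted_results):
        res = small_fitted_results
        a = res.simulate(n_replicates=5, master_seed=123)
        b = res.simulate(n_replicates=5, master_seed=123)
        assert a == b

    def test_different_seed_differs(self, small_fitted_results):
        res = small_fitted_results
        a = res.simulate(n_replicates=5, master_seed=123)
        b = res.simulate(n_replicates=5, master_seed=124)
        assert not np.array_equal(a.counts, b.counts)

    def test_single_replicate_average_equals_counts(self):
        cfg = cs.SyntheticConfig(n_persons=200, seed=8)
        cohort = cs.generate_cohort(cfg)
        t = uniform_table(2001, 2003, risks_by_event=[0.05, 0.01, 0.01, 0.01, 0.01])
        sim = cs.run_replicates(cohort, t, 2001, 2003, n_replicates=1, master_seed=9)
        assert np.array_equal(sim.averaged, sim.counts[0].astype(float))

    def test_replicates_must_be_positive(self, small_fitted_results):
        with pytest.raises(cs.DomainError):
            small_fitted_results.simulate(n_replicates=0)

    def test_binomial_oracle_for_single_year_pci(self):
        """10,000 no-history persons, Pr(PCI) = 0.05, no follow-on risks:
        the replicate-averaged PCI count is binomial with mean 500."""
        n = 10_000
        cohort = cs.BaselineCohort(
            ids=[f"p{i}" for i in range(n)],
            sex_idx=np.zeros(n, dtype=int),
            age=np.full(n, 50),
            state=np.zeros(n, dtype=int),
        )
        t = uniform_table(2001, 2001)
        t.values[:, :, :, int(HistoryState.NO_HISTORY), int(EventType.PCI)] = 0.05
        sim = cs.run_replicates(cohort, t, 2001, 2001, n_replicates=100,
                                master_seed=31)
        mean_pci = sim.averaged[0, int(EventType.PCI)]
        se = np.sqrt(n * 0.05 * 0.95 / 100)  # ~2.18
        assert abs(mean_pci - 500.0) < 4 * se

    def test_counts_csv_round_trip(self, tmp_path, small_fitted_results):
        sim = small_fitted_results.simulate(n_replicates=3, master_seed=1)
        sim.write_csv(tmp_path)
        import pandas as pd

        back = pd.read_csv(tmp_path / "replicate_counts.csv")
        total = back["count"].sum()
        assert total == sim.counts.sum()
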