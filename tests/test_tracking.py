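"""Single-cell mEC/EC/NEC classification, clone tracking, tissue intersection."""

import pytest

from clonotrack import (
    Compartment,
    build_ground_truth,
    classify_single_cell,
    filter_functional,
    intersect_tissues,
    sample_cells,
    track_clones,
    tracking_long_table,
)
from clonotrack.errors import PlatformError, SubjectMismatchError, TissueMismatchError
from clonotrack.tracking import EC, MEC, NEC
from conftest import make_sample, make_sc_sample


class TestClassifySingleCell:
    def test_textbook_case(self, named_keys):
        counts = {"A": 8, "B": 2, "C": 1, "D": 1}
        keys = named_keys(counts)
        r = classify_single_cell(make_sc_sample(counts))
        assert r.labels[keys["A"]] == MEC
        assert r.labels[keys["B"]] == EC
        assert r.labels[keys["C"]] == r.labels[keys["D"]] == NEC
        assert r.mec_key == keys["A"]

    def test_all_singletons_no_mec(self):
        r = classify_single_cell(make_sc_sample({"A": 1, "B": 1, "C": 1}))
        assert set(r.labels.values()) == {NEC}
        assert r.mec_key is None and not r.mec_tied

    def test_tie_leaves_mec_undesignated(self, named_keys):
        counts = {"A": 5, "B": 5, "C": 1}
        keys = named_keys(counts)
        r = classify_single_cell(make_sc_sample(counts))
        assert r.labels[keys["A"]] == r.labels[keys["B"]] == EC
        assert r.labels[keys["C"]] == NEC
        assert r.mec_key is None and r.mec_tied

    def test_partitions_all_clones(self):
        counts = {"A": 3, "B": 2, "C": 1, "D": 1, "E": 4}
        r = classify_single_cell(make_sc_sample(counts))
        assert len(r.ec_keys) + len(r.nec_keys) == len(counts)

    def test_bulk_sample_rejected(self):
        with pytest.raises(PlatformError):
            classify_single_cell(make_sample({"A": 3}))


class TestTrackClones:
    def _two_timepoints(self, counts_t0, counts_t1):
        return [
            make_sc_sample(counts_t0, sample_id="s0", timepoint="t0"),
            make_sc_sample(counts_t1, sample_id="s1", timepoint="t1"),
        ]

    def test_ec_at_both_timepoints_is_persistent(self, named_keys):
        counts = {"A": 5, "B": 1}
        keys = named_keys(counts)
        m = track_clones(self._two_timepoints({"A": 5, "B": 1}, {"A": 3, "B": 1}))
        assert m.persistent[keys["A"]] is True
        assert m.persistent[keys["B"]] is False

    def test_clone_present_once_kept_with_zero_column(self, named_keys):
        counts = {"A": 5, "B": 2}
        keys = named_keys(counts)
        m = track_clones(self._two_timepoints({"A": 5, "B": 2}, {"A": 7}))
        assert m.persistent[keys["B"]] is False
        assert m.frequencies.at[keys["B"], "s1"] == 0.0

    def test_row_sums_per_sample_are_one(self):
        m = track_clones(self._two_timepoints({"A": 5, "B": 2}, {"A": 3, "C": 4}))
        sums = m.frequencies.sum(axis=0)
        assert all(abs(v - 1.0) < 1e-12 for v in sums)

    def test_ci_j_ordering_by_mean_frequency(self, named_keys):
        # A, B, C persistent with mean frequencies 0.5 > 0.3 > 0.2
        counts = {"A": 50, "B": 30, "C": 20}
        keys = named_keys(counts)
        m = track_clones(
            self._two_timepoints({"A": 50, "B": 30, "C": 20},
                                 {"A": 50, "B": 30, "C": 20}),
            subject_index=1,
        )
        assert m.clone_ids[keys["A"]] == "C1.1"
        assert m.clone_ids[keys["B"]] == "C1.2"
        assert m.clone_ids[keys["C"]] == "C1.3"

    def test_subject_index_parsed_from_id(self, named_keys):
        counts = {"A": 5}
        samples = [
            make_sc_sample({"A": 5}, sample_id="s0", timepoint="t0", subject_id="RA2"),
            make_sc_sample({"A": 5}, sample_id="s1", timepoint="t1", subject_id="RA2"),
        ]
        m = track_clones(samples)
        assert m.clone_ids[named_keys(counts)["A"]] == "C2.1"

    def test_label_stability_under_reordering(self):
        s = self._two_timepoints({"A": 40, "B": 30, "C": 2}, {"A": 30, "B": 40, "C": 2})
        assert track_clones(s).clone_ids == track_clones(list(reversed(s))).clone_ids

    def test_mixed_subjects_rejected(self):
        samples = [
            make_sc_sample({"A": 5}, sample_id="s0", subject_id="RA1"),
            make_sc_sample({"A": 5}, sample_id="s1", subject_id="RA2"),
        ]
        with pytest.raises(SubjectMismatchError):
            track_clones(samples)

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError):
            track_clones([make_sc_sample({"A": 5})])

    def test_long_table_shape(self):
        m = track_clones(self._two_timepoints({"A": 5, "B": 2}, {"A": 3}))
        table = tracking_long_table(m)
        assert len(table) == 2 * len(m.frequencies.index)
        assert set(table.columns) == {
            "clone_key", "sample_id", "frequency", "persistent", "clone_id"
        }


class TestPersistenceRecoveryPower:
    def test_dominant_clones_recovered_across_seeds(self):
        """Designated clones at >= 5% true frequency are flagged persistent in
        >= 95% of repeated noise-free 102-cell studies."""
        comps = [Compartment("PB", "memory", t) for t in ("t0", "t1", "t2")]
        truth = build_ground_truth(
            300, 2, 1.0, comps, seed=11, dominant_freqs=[0.10, 0.05]
        )
        dominant = truth.designated_persistent
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            samples = [
                filter_functional(sample_cells(truth, c, 102, seed=seed * 10 + i))
                for i, c in enumerate(comps)
            ]
            m = track_clones(samples)
            if all(m.persistent.get(k, False) for k in dominant):
                hits += 1
        assert hits >= 0.95 * n_seeds


class TestIntersectTissues:
    def test_disjoint_tissues_empty(self):
        pb = make_sample({"a": 5, "b": 5}, sample_id="pb")
        syn = make_sample({"a": 0, "b": 0, "c": 5}, sample_id="syn", tissue="synovium")
        syn.clonotypes = [c for c in syn.clonotypes if c.count > 0]
        assert intersect_tissues([pb], syn) == set()

    def test_synovium_subset_of_pb(self):
        pb = make_sample({"a": 5, "b": 5, "c": 5}, sample_id="pb")
        syn = make_sample({"a": 2, "b": 1}, sample_id="syn", tissue="synovium")
        assert intersect_tissues([pb], syn) == syn.clone_keys()

    def test_wrong_tissue_rejected(self):
        pb = make_sample({"a": 5}, sample_id="pb")
        with pytest.raises(TissueMismatchError):
            intersect_tissues([pb], make_sample({"a": 5}, sample_id="x"))

    def test_simulator_seeded_clones_recovered_exactly(self):
        """Deep noise-free sampling of both tissues recovers exactly the five
        clones placed in the synovium by construction."""
        comps = [
            Compartment("PB", "memory", "t0"),
            Compartment("synovium", "memory", "t0"),
        ]
        truth = build_ground_truth(
            200, 5, 1.0, comps, seed=3, synovium_share=0.0
        )
        from clonotrack import NoiseModel, sample_bulk

        pb = filter_functional(
            sample_bulk(truth, comps[0], 200_000, NoiseModel(seed=1))
        )
        syn = filter_functional(
            sample_bulk(truth, comps[1], 200_000, NoiseModel(seed=2))
        )
        assert intersect_tissues([pb], syn) == truth.designated_persistent
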