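import numpy as np
import pytest

from biletree import (
    NoiseModel,
    classify_dataset,
    classify_spectrum,
    default_dihydroxy_profiles,
    generate_spectrum,
    load_tree,
    node_scan_sets,
    normalize,
)
from biletree.errors import TreeConfigError
from biletree.queries import IonPresence

from conftest import make_relative

MINIMAL_CONFIG = {
    "tree_name": "custom",
    "root": {
        "name": "root",
        "predicates": [{"type": "presence", "target_mz": 321.26, "tol_mz": 0.05}],
        "children": [
            {"name": "left", "predicates": [{"type": "presence", "target_mz": 161.132}]},
            {"name": "right", "predicates": [{"type": "absence", "target_mz": 161.132,
                                              "max_rel_intensity": 1.0}]},
        ],
    },
}


class TestLoadTree:
    def test_minimal_config(self):
        tree = load_tree(MINIMAL_CONFIG)
        assert len(list(tree.iter_nodes())) == 3
        assert tree.leaf_names() == ["left", "right"]

    def test_duplicate_node_name_rejected(self):
        config = {
            "tree_name": "dup",
            "root": {
                "name": "root",
                "predicates": [{"type": "presence", "target_mz": 100.0}],
                "children": [
                    {"name": "leaf", "predicates": [{"type": "presence", "target_mz": 101.0}]},
                    {"name": "leaf", "predicates": [{"type": "presence", "target_mz": 102.0}]},
                ],
            },
        }
        with pytest.raises(TreeConfigError, match="leaf"):
            load_tree(config)

    def test_node_without_predicates_rejected(self):
        config = {"tree_name": "bad", "root": {"name": "root", "predicates": []}}
        with pytest.raises(TreeConfigError, match="root"):
            load_tree(config)

    def test_builtin_dihydroxy_root_has_class_ions(self, dihydroxy_tree):
        targets = {
            p.target_mz
            for p in dihydroxy_tree.root.query.predicates
            if isinstance(p, IonPresence)
        }
        assert {321.26, 339.27} <= targets


class TestClassifySpectrum:
    def test_ketone_branch(self, dihydroxy_tree):
        s = make_relative([(480.28, 100.0), (321.26, 50.0), (339.27, 50.0), (161.132, 20.0)])
        a = classify_spectrum(s, dihydroxy_tree)
        assert a.terminal_bin == "ketone"
        assert not a.ambiguous
        assert a.node_path == ("Dihydroxy", "ketone")

    def test_root_failure_gives_empty_path(self, dihydroxy_tree):
        s = make_relative([(480.28, 100.0), (161.132, 20.0)])
        a = classify_spectrum(s, dihydroxy_tree)
        assert a.node_path == ()
        assert a.terminal_bin is None
        assert not a.root_matched

    def test_two_sibling_leaves_gives_ambiguity(self, dihydroxy_tree):
        s = make_relative([(482.29, 100.0), (321.26, 50.0), (339.27, 50.0),
                           (201.163, 10.0), (211.147, 2.0), (253.195, 8.0), (271.206, 8.0)])
        a = classify_spectrum(s, dihydroxy_tree)
        assert a.ambiguous
        assert a.terminal_bin is None
        assert sorted(a.matched_bins) == ["3,12a-(OH)2", "7,12a-(OH)2"]

    def test_dead_end_records_deepest_satisfied_node(self, dihydroxy_tree):
        # class ions and high ratio, but no leaf marker ion at all
        s = make_relative([(482.29, 100.0), (321.26, 50.0), (339.27, 50.0),
                           (201.163, 10.0), (211.147, 2.0)])
        a = classify_spectrum(s, dihydroxy_tree)
        assert a.root_matched
        assert a.terminal_bin is None and not a.ambiguous
        assert a.node_path[-1] == "3,12a-(OH)2; 7,12a-(OH)2"


class TestClassifyDataset:
    def test_empty_input(self, dihydroxy_tree):
        assert classify_dataset([], [dihydroxy_tree]) == []

    def test_no_trees_rejected(self):
        with pytest.raises(ValueError):
            classify_dataset([], [])

    def test_labelled_batch_fully_recovered(self, dihydroxy_tree, noise_free_benchmark):
        spectra, labels = noise_free_benchmark
        assignments = classify_dataset(spectra, [dihydroxy_tree])
        assert len(assignments) == len(spectra)
        truth = dict(zip(labels["scan_id"], labels["true_label"]))
        assert all(a.terminal_bin == truth[a.scan_id] for a in assignments)

    def test_root_gating_limits_records(self, dihydroxy_tree):
        inside = make_relative([(482.29, 100.0), (321.26, 50.0), (339.27, 50.0)], scan_id="in")
        outside = make_relative([(482.29, 100.0)], scan_id="out")
        assignments = classify_dataset([inside, outside], [dihydroxy_tree])
        assert [a.scan_id for a in assignments] == ["in"]

    def test_determinism(self, dihydroxy_tree, noise_free_benchmark):
        spectra, _ = noise_free_benchmark
        a1 = classify_dataset(spectra, [dihydroxy_tree])
        a2 = classify_dataset(spectra, [dihydroxy_tree])
        assert a1 == a2


class TestPathSubsetProperty:
    def test_scan_set_at_node_subset_of_parent(self, dihydroxy_tree):
        # randomized spectra: noisy draws from every profile, heavy dropout so
        # spectra scatter over all tree depths
        profiles = default_dihydroxy_profiles()
        noise = NoiseModel(intensity_cv=0.6, n_noise_peaks=25, dropout_max_prob=0.8,
                           dropout_scale=15.0, mz_jitter_sd=0.004)
        rng = np.random.default_rng(7)
        spectra = []
        for i in range(300):
            spectrum, _ = generate_spectrum(profiles[i % len(profiles)], noise, rng, scan_id=str(i))
            spectra.append(normalize(spectrum))
        sets = node_scan_sets(spectra, dihydroxy_tree)
        parents = dihydroxy_tree.parent_of()
        checked = 0
        for node, parent in parents.items():
            if parent is not None:
                assert sets[node] <= sets[parent]
                checked += 1
        assert checked >= 7  # every non-root node of the dihydroxy tree
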