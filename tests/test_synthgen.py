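import numpy as np
import pytest
from scipy.stats import spearmanr

import dendropy

from degenkit.degeneracy import IUPAC_SETS, degen1_matrix
from degenkit.charsets import build_named_set
from degenkit.composition import base_composition, euclidean_matrix
from degenkit.errors import DegenkitError
from degenkit.indels import gap_events, quality_filter
from degenkit.synthgen import (
    IndelPlanEntry,
    SimSpec,
    default_spec,
    inject_indels,
    simulate_alignment,
)


def pairwise_conflict_distance(m, i, j):
    """Fraction of comparable sites whose symbol sets cannot intersect."""
    a, b = m.rows[i], m.rows[j]
    n = conflicts = 0
    for x, y in zip(a, b):
        sx, sy = IUPAC_SETS.get(x, frozenset()), IUPAC_SETS.get(y, frozenset())
        if not sx or not sy or "N" in (x, y):
            continue
        n += 1
        if not sx & sy:
            conflicts += 1
    return conflicts / n if n else 0.0


def tree_path_distances(newick, taxa):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    out = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            out[(a, b)] = pdm.patristic_distance(tns.get_taxon(a), tns.get_taxon(b))
    return out


class TestSimulateAlignment:
    def test_same_seed_identical(self):
        spec = default_spec(n_taxa=8, seed=5, n_fragments=2, n_codons=20)
        assert simulate_alignment(spec) == simulate_alignment(spec)

    def test_different_seed_differs(self):
        a = default_spec(n_taxa=8, seed=5, n_fragments=2, n_codons=20)
        b = default_spec(n_taxa=8, seed=6, n_fragments=2, n_codons=20)
        assert simulate_alignment(a) != simulate_alignment(b)

    def test_missing_taxa_rendered_as_question_marks(self):
        spec = default_spec(n_taxa=8, seed=5, n_fragments=2, n_codons=20)
        m = simulate_alignment(spec)
        frag0 = m.charsets["frag01"]
        for t in spec.missing_taxa[0]:
            row = m.row(t)
            assert all(row[c] == "?" for c in frag0)

    def test_no_synonymous_change_means_no_fourfold_nt3_differences(self):
        spec = default_spec(
            n_taxa=10, seed=3, n_fragments=3, n_codons=40,
            syn_rate_multiplier=0.0, biased=False,
        )
        spec.missing_taxa = {}
        m = simulate_alignment(spec)
        ff = build_named_set(m, "nt3_4foldsynon")
        for c in range(ff.n_cols):
            col = [s for s in ff.column(c) if s != "N"]
            assert len(set(col)) <= 1, f"synonymous difference at codon {c}"

    def test_json_round_trip(self):
        spec = default_spec(n_taxa=6, seed=1, n_fragments=2, n_codons=10)
        spec.indel_plan = [IndelPlanEntry(0, 2, 4, ("t01", "t02"))]
        back = SimSpec.from_json(spec.to_json())
        assert back == spec

    def test_invalid_spec_rejected(self):
        with pytest.raises(DegenkitError):
            SimSpec(newick="(a,b);", syn_rate_multiplier=-1)
        with pytest.raises(DegenkitError):
            SimSpec(newick="(a,b);", n_codons=5,
                    indel_plan=[IndelPlanEntry(0, 2, 9, ("a",))])


class TestInjectIndels:
    def test_plant_and_recover_exact(self):
        spec = default_spec(n_taxa=10, seed=7, n_fragments=3, n_codons=30)
        spec.missing_taxa = {}
        plan = [
            IndelPlanEntry(0, 5, 8, ("t01", "t02", "t03")),
            IndelPlanEntry(1, 0, 4, ("t04", "t05")),
            IndelPlanEntry(2, 10, 11, ("t06", "t07")),
        ]
        spec.indel_plan = plan
        m = inject_indels(simulate_alignment(spec), spec)
        survivors = quality_filter(gap_events(m))
        assert len(survivors) == len(plan)
        got = {(e.fragment, e.start, e.end, e.taxa) for e in survivors}
        for e in plan:
            frag = f"frag{e.fragment + 1:02d}"
            start = e.fragment * 90 + 3 * e.codon_start
            end = e.fragment * 90 + 3 * e.codon_end
            assert (frag, start, end, frozenset(e.taxa)) in got

    def test_no_false_positives_on_gap_free_simulation(self):
        spec = default_spec(n_taxa=10, seed=7, n_fragments=3, n_codons=30)
        spec.missing_taxa = {}
        assert gap_events(simulate_alignment(spec)) == []

    def test_staggered_decoy_rejected(self):
        spec = default_spec(n_taxa=10, seed=7, n_fragments=2, n_codons=30)
        spec.missing_taxa = {}
        spec.indel_plan = [
            IndelPlanEntry(0, 5, 8, ("t01", "t02")),
            IndelPlanEntry(0, 5, 9, ("t03",)),
        ]
        m = inject_indels(simulate_alignment(spec), spec)
        assert quality_filter(gap_events(m)) == []

    def test_overlap_with_existing_gap_rejected(self):
        spec = default_spec(n_taxa=10, seed=7, n_fragments=2, n_codons=30)
        spec.missing_taxa = {}
        spec.indel_plan = [
            IndelPlanEntry(0, 5, 8, ("t01",)),
            IndelPlanEntry(0, 6, 7, ("t01",)),
        ]
        with pytest.raises(DegenkitError):
            inject_indels(simulate_alignment(spec), spec)


class TestSignalSeparation:
    def test_degen1_tracks_tree_better_than_nt3_under_bias(self):
        """Fast biased synonymous change misleads; degen1 removes it."""
        spec = default_spec(n_taxa=16, seed=13, n_fragments=6, n_codons=60,
                           syn_rate_multiplier=10.0, biased=True)
        spec.missing_taxa = {}
        m = simulate_alignment(spec)
        true_d = tree_path_distances(spec.newick, m.taxa)
        deg = degen1_matrix(m)
        nt3 = build_named_set(m, "nt3")
        pairs = list(true_d)
        t = [true_d[p] for p in pairs]
        idx = {tx: i for i, tx in enumerate(m.taxa)}
        d_deg = [pairwise_conflict_distance(deg, idx[a], idx[b]) for a, b in pairs]
        d_nt3 = [pairwise_conflict_distance(nt3, idx[a], idx[b]) for a, b in pairs]
        rho_deg = spearmanr(t, d_deg).statistic
        rho_nt3 = spearmanr(t, d_nt3).statistic
        assert rho_deg > rho_nt3

    def test_biased_groups_cluster_by_composition_not_phylogeny(self):
        spec = default_spec(n_taxa=16, seed=13, n_fragments=6, n_codons=60,
                           syn_rate_multiplier=10.0, biased=True)
        spec.missing_taxa = {}
        m = simulate_alignment(spec)
        ff = build_named_set(m, "nt3_4foldsynon")
        labels, d = euclidean_matrix(base_composition(ff))
        groups = {t: g for g, ts in spec.groups.items() for t in ts}
        within, between = [], []
        for i, a in enumerate(labels):
            for j in range(i + 1, len(labels)):
                (within if groups[a] == groups[labels[j]] else between).append(d[i, j])
        assert np.mean(between) > 2 * np.mean(within)
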