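"""Markov generator: stationary law, analytic pair counts, presets, codons."""

import numpy as np
import pytest
from scipy import stats

from dipasym import (
    MarkovModel,
    SequenceSet,
    analytic_c190,
    count_pairs,
    expected_pair_count,
    generate_proteins,
    make_preset,
    reverse_translate,
    stationary_distribution,
    translate,
)
from dipasym.counting import AA_TO_INDEX, encode_residues
from dipasym.sequence_io import STANDARD_RESIDUES
from dipasym.synthetic import SYNONYMOUS_CODONS


def power_iteration_stationary(transition, n_iter=10_000, tol=1e-14):
    """Independent brute-force oracle for the stationary distribution."""
    pi = np.full(20, 1 / 20)
    for _ in range(n_iter):
        nxt = pi @ transition
        if np.abs(nxt - pi).max() < tol:
            return nxt
        pi = nxt
    return pi


def random_stochastic_model(rng):
    t = rng.random((20, 20)) + 0.05
    t /= t.sum(axis=1, keepdims=True)
    init = rng.random(20)
    init /= init.sum()
    return MarkovModel(initial=init, transition=t)


def test_deterministic_chain_generates_constant_sequences():
    init = np.zeros(20)
    init[AA_TO_INDEX["A"]] = 1.0
    t = np.zeros((20, 20))
    t[:, AA_TO_INDEX["A"]] = 1.0
    model = MarkovModel(initial=init, transition=t)
    seqs = generate_proteins(model, 3, 10, seed=0)
    assert all(s.residues == "A" * 10 for s in seqs)


def test_non_stochastic_model_rejected():
    bad = np.full((20, 20), 1 / 20)
    bad[0, 0] += 0.1
    with pytest.raises(ValueError):
        MarkovModel(initial=np.full(20, 1 / 20), transition=bad)


def test_generation_is_seed_deterministic(symmetric_preset):
    a = generate_proteins(symmetric_preset.model, 5, 50, seed=42)
    b = generate_proteins(symmetric_preset.model, 5, 50, seed=42)
    assert a == b


def test_uniform_chain_residue_frequencies(symmetric_preset):
    seqs = generate_proteins(symmetric_preset.model, 200, 200, seed=1)
    observed = np.zeros(20)
    for s in seqs:
        observed += np.bincount(encode_residues(s.residues), minlength=20)
    chi2 = ((observed - observed.sum() / 20) ** 2 / (observed.sum() / 20)).sum()
    assert chi2 < stats.chi2.ppf(0.999, df=19)


def test_empirical_transitions_recover_matrix(rng):
    model = random_stochastic_model(np.random.default_rng(77))
    seqs = generate_proteins(model, 500, 400, seed=78)
    counts = count_pairs(seqs).counts.astype(float)
    row_totals = counts.sum(axis=1, keepdims=True)
    observed = counts / row_totals
    se = np.sqrt(model.transition * (1 - model.transition) / row_totals)
    assert (np.abs(observed - model.transition) <= 3.5 * se + 1e-12).mean() > 0.985


def test_stationary_uniform_cases(symmetric_preset):
    np.testing.assert_allclose(
        stationary_distribution(symmetric_preset.model), np.full(20, 1 / 20)
    )
    # doubly stochastic: permutation-mixture matrix
    rng = np.random.default_rng(5)
    t = np.full((20, 20), 1 / 40)
    perm = rng.permutation(20)
    for i, j in enumerate(perm):
        t[i, j] += 0.5
    model = MarkovModel(initial=np.full(20, 1 / 20), transition=t)
    np.testing.assert_allclose(
        stationary_distribution(model), np.full(20, 1 / 20), atol=1e-12
    )


def test_stationary_matches_power_iteration_oracle():
    for seed in (1, 2, 3):
        model = random_stochastic_model(np.random.default_rng(seed))
        pi = stationary_distribution(model)
        oracle = power_iteration_stationary(model.transition)
        np.testing.assert_allclose(pi, oracle, atol=1e-10)
        np.testing.assert_allclose(pi @ model.transition, pi, atol=1e-12)


def test_reducible_chain_rejected():
    t = np.eye(20)
    with pytest.raises(ValueError):
        stationary_distribution(MarkovModel(np.full(20, 1 / 20), t))


def test_expected_pair_count_uniform_closed_form(symmetric_preset):
    e = expected_pair_count(symmetric_preset.model, gap=0, length=101)
    np.testing.assert_allclose(e, np.full((20, 20), 100 / 400))
    e5 = expected_pair_count(symmetric_preset.model, gap=5, length=101)
    np.testing.assert_allclose(e5, np.full((20, 20), 95 / 400))


def test_expected_pair_count_matches_simulation(asymmetric_preset):
    model = asymmetric_preset.model
    n, length, gap = 3000, 60, 5
    seqs = generate_proteins(model, n, length, seed=9)
    observed = count_pairs(seqs, gap=gap).counts / n
    expected = expected_pair_count(model, gap=gap, length=length)
    se = np.sqrt(expected / n)  # Poisson-scale error on a per-sequence mean
    assert (np.abs(observed - expected) <= 4 * se).mean() > 0.99


def test_analytic_c190_zero_under_detailed_balance(symmetric_preset):
    for pair in ("AC", "EP", "WY"):
        assert analytic_c190(symmetric_preset.model, pair) == pytest.approx(0.0)


def test_analytic_c190_empirical_convergence(asymmetric_preset):
    seqs = generate_proteins(asymmetric_preset.model, 1500, 400, seed=21)
    counts = count_pairs(seqs)
    for pair, expected in asymmetric_preset.engineered_pairs:
        i, j = AA_TO_INDEX[pair[0]], AA_TO_INDEX[pair[1]]
        n_ab, n_ba = counts.counts[i, j], counts.counts[j, i]
        observed = 200 * abs(int(n_ab) - int(n_ba)) / (n_ab + n_ba)
        noise = 200 / np.sqrt(n_ab + n_ba)
        assert observed == pytest.approx(expected, abs=4 * noise)


def test_preset_self_consistency_and_determinism():
    p1 = make_preset("table3_asymmetric")
    p2 = make_preset("table3_asymmetric")
    np.testing.assert_array_equal(p1.model.transition, p2.model.transition)
    assert p1.engineered_pairs == p2.engineered_pairs
    for pair, value in p1.engineered_pairs:
        assert analytic_c190(p1.model, pair) == pytest.approx(value, abs=1e-9)
    sym = make_preset("symmetric")
    assert all(v == 0.0 for _, v in sym.engineered_pairs)
    with pytest.raises(ValueError):
        make_preset("no_such_preset")


def test_preset_targets_are_approximated(asymmetric_preset):
    targets = {"EP": 33.76, "PW": 24.14, "MW": 24.12, "GP": 22.61,
               "AM": 21.85, "IP": 21.07, "CP": 20.97}
    engineered = dict(asymmetric_preset.engineered_pairs)
    for pair, target in targets.items():
        assert engineered[pair] == pytest.approx(target, abs=0.2)


def test_gap5_analytic_asymmetry_attenuates(asymmetric_preset):
    for pair, _ in asymmetric_preset.engineered_pairs:
        assert analytic_c190(asymmetric_preset.model, pair, gap=5) < analytic_c190(
            asymmetric_preset.model, pair, gap=0
        )


def test_single_codon_residues_reverse_translate_uniquely(symmetric_preset):
    from dipasym import ProteinSequence

    (cds,) = reverse_translate(
        SequenceSet([ProteinSequence("s", "MW")]), seed=0
    )
    assert cds.bases == "ATGTGG"


def test_reverse_translate_roundtrip(symmetric_preset):
    prots = generate_proteins(symmetric_preset.model, 30, 90, seed=13)
    genes = reverse_translate(prots, seed=14)
    for gene, prot in zip(genes, prots):
        assert translate(gene).residues == prot.residues


def test_reverse_translate_codon_usage_uniform(symmetric_preset):
    from dipasym import ProteinSequence

    prots = SequenceSet([ProteinSequence("s", "L" * 6000)])
    (cds,) = reverse_translate(prots, seed=15)
    codons = [cds.bases[i : i + 3] for i in range(0, len(cds.bases), 3)]
    observed = [codons.count(c) for c in SYNONYMOUS_CODONS["L"]]
    chi2, p = stats.chisquare(observed)
    assert p > 1e-4


def test_reverse_translate_rejects_unknown_residue():
    from dipasym import ProteinSequence

    with pytest.raises(ValueError, match="without codons"):
        reverse_translate(SequenceSet([ProteinSequence("s", "MA*G")]), seed=0)


def test_model_tsv_roundtrip(tmp_path, asymmetric_preset):
    path = tmp_path / "model.tsv"
    asymmetric_preset.model.to_tsv(path)
    again = MarkovModel.from_tsv(path)
    np.testing.assert_allclose(again.transition, asymmetric_preset.model.transition)
    np.testing.assert_allclose(again.initial, asymmetric_preset.model.initial)
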