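"""Mutational characterization metrics against hand counts and naive oracles."""

import numpy as np
import pandas as pd
import pytest

import mitocohort as mc
from mitocohort import simulate as sim
from mitocohort.calling import build_cohort_calls
from mitocohort.metrics import unit_lengths

from naive_metrics import (
    naive_aa_change_counts,
    naive_definite_class_counts,
    naive_diversity_volume,
)


def _toy_registry():
    """Five variant types across three genes, hand-countable."""
    rows = [
        # m_notation, position, ref, alt, kind, carriers, definite,
        # transition, gene, macrodivision, synonymy
        ("m.100A>G", 100, "A", "G", "substitution", 3, True, True,
         "D-loop", "D-loop", "not-protein"),
        ("m.3400T>C", 3400, "T", "C", "substitution", 2, True, True,
         "ND1", "NDs", "nonsynonymous"),
        ("m.3460G>A", 3460, "G", "A", "substitution", 1, True, True,
         "ND1", "NDs", "synonymous"),
        ("m.14850C>A", 14850, "C", "A", "substitution", 4, True, False,
         "CYB", "CYB", "synonymous"),
        ("m.300del", 300, "A", "", "deletion", 2, False, None,
         "D-loop", "D-loop", "not-protein"),
    ]
    return pd.DataFrame(
        rows,
        columns=["m_notation", "position", "ref", "alt", "kind",
                 "carrier_count", "definite", "transition", "gene",
                 "macrodivision", "synonymy"],
    ).assign(codon_number=None, aa_ref=None, aa_alt=None)


def test_toy_registry_hand_counts():
    table = mc.diversity_and_volume(_toy_registry(), grouping="gene")
    assert table.loc["D-loop", "diversity"] == 2
    assert table.loc["D-loop", "volume"] == 5
    assert table.loc["D-loop", "diversity_indel"] == 1
    assert table.loc["ND1", "diversity"] == 2
    assert table.loc["ND1", "diversity_synonymous"] == 1
    assert table.loc["ND1", "diversity_nonsynonymous"] == 1
    assert table.loc["CYB", "volume"] == 4
    genome = mc.diversity_and_volume(_toy_registry(), grouping="genome")
    assert genome.loc["genome", "diversity"] == 5
    assert genome.loc["genome", "volume"] == 12


def test_two_participants_sharing_a_variant():
    reg = pd.DataFrame(
        [("m.100A>G", 100, "A", "G", "substitution", 2, True, True,
          "D-loop", "D-loop", "not-protein", None, None, None)],
        columns=_toy_registry().columns,
    )
    table = mc.diversity_and_volume(reg, grouping="genome")
    assert table.loc["genome", "diversity"] == 1
    assert table.loc["genome", "volume"] == 2


def test_single_participant_diversity_equals_volume(ref):
    cfg = sim.SimulationConfig(
        n_participants=1, variants=sim.default_variant_panel(),
        ambiguity_rate=0.0, seed=5,
    )
    cohort = sim.simulate_cohort(cfg, ref)
    calls = mc.call_cohort(cohort.sequences, ref)
    for grouping in ("gene", "macrodivision", "genome"):
        table = mc.diversity_and_volume(calls.registry, grouping)
        assert (table["diversity"] == table["volume"]).all()


def test_diversity_density_arithmetic():
    assert mc.diversity_density(10, 5, 2.0) == 1.0
    assert mc.diversity_density(0, 5, 2.0) == 0.0
    with pytest.raises(ValueError):
        mc.diversity_density(10, 0, 2.0)


def test_density_table_matches_spreadsheet_style_recalc(ref):
    reg = _toy_registry()
    n = 10
    table = mc.diversity_density_table(reg, ref, n_samples=n, grouping="gene")
    lengths = unit_lengths(ref, "gene")
    dv = mc.diversity_and_volume(reg, "gene")
    for gene in dv.index:
        expected = dv.loc[gene, "diversity"] / n / (lengths[gene] / 1000.0)
        assert np.isclose(table.loc[gene, "density"], expected)


def test_macrodivision_lengths_derived_from_features(ref):
    lengths = unit_lengths(ref, "macrodivision")
    assert lengths["D-loop"] == (16569 - 16024 + 1) + 576
    assert lengths["CYB"] == 15887 - 14747 + 1
    assert set(lengths.index) == set(
        ["D-loop", "RNRs", "tRNAs", "NDs", "COs", "ATPs", "CYB"]
    )


def test_relative_diversity_arithmetic():
    assert np.isclose(mc.relative_diversity(1075, 8291), 0.129658, atol=1e-6)
    assert mc.relative_diversity(0, 8291) == 0.0
    with pytest.raises(ValueError, match="exceeds"):
        mc.relative_diversity(10, 5)


def test_relative_diversity_invariant_to_duplicating_participants(
    ref, space, small_calls
):
    doubled = {
        f"{sid}+{k}": calls
        for sid, calls in small_calls.per_sample.items()
        for k in (0, 1)
    }
    reg2 = build_cohort_calls(doubled).registry
    t1 = mc.relative_diversity_table(small_calls.registry, space)
    t2 = mc.relative_diversity_table(reg2, space)
    pd.testing.assert_series_equal(
        t1["relative_diversity"], t2["relative_diversity"]
    )


def test_momentum_exact_linear_relationship(space):
    k = 2.5e-4
    observed = space.per_gene["possible_synonymous"] * k * 10
    res = mc.momentum(observed, n_samples=10, space=space, cls="synonymous")
    assert np.isclose(res.slope, k)
    assert np.isclose(res.r_squared, 1.0)


def test_momentum_zero_observed(space):
    observed = pd.Series(0.0, index=space.per_gene.index)
    res = mc.momentum(observed, n_samples=5, space=space)
    assert res.slope == 0.0


def test_momentum_matches_closed_form_and_gene_order(space):
    rng = np.random.default_rng(8)
    observed = pd.Series(
        rng.integers(0, 50, size=len(space.per_gene)).astype(float),
        index=space.per_gene.index,
    )
    n = 20
    res = mc.momentum(observed, n, space, cls="nonsynonymous")
    x = space.per_gene["possible_nonsynonymous"].to_numpy(dtype=float)
    y = (observed / n).to_numpy()
    slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
    assert np.isclose(res.slope, slope)
    shuffled = observed.sample(frac=1.0, random_state=1)
    assert np.isclose(
        mc.momentum(shuffled, n, space, cls="nonsynonymous").slope, res.slope
    )


def test_amino_acid_change_matrix_single_type(ref, space):
    # find a Thr->Ala change in the enumerated space and register it
    feat = ref.feature("ND5")
    found = None
    for pos in range(feat.start, feat.end + 1):
        for alt in "ACGT":
            if alt == ref.base(pos):
                continue
            _, aa_ref, aa_alt, syn = ref.classify_substitution(feat, pos, alt)
            if (aa_ref, aa_alt) == ("T", "A"):
                found = (pos, ref.base(pos), alt)
                break
        if found:
            break
    pos, base, alt = found
    reg = pd.DataFrame(
        [(f"m.{pos}{base}>{alt}", pos, base, alt, "substitution", 2, True,
          True, "ND5", "NDs", "nonsynonymous", 1, "T", "A")],
        columns=_toy_registry().columns,
    )
    matrix = mc.amino_acid_changes(reg, space, n_samples=4)
    assert matrix.observed.loc["T", "A"] == 1
    assert matrix.observed.to_numpy().sum() == 1
    assert matrix.most_prevalent[:2] == ("T", "A")
    assert 0.0 < matrix.bias["A"] <= 1.0
    assert np.isclose(
        matrix.bias_density["A"], matrix.bias["A"] / 4.0
    )
    assert (matrix.bias.fillna(0) <= 1.0).all()


def test_physicochemical_prevalence_sums_to_100(ref, space):
    rng = np.random.default_rng(4)
    aas = list(space.max_changes_to_aa.index)
    observed = pd.DataFrame(
        rng.integers(0, 5, size=(20, 20)), index=aas, columns=aas
    )
    np.fill_diagonal(observed.values, 0)
    matrix = mc.AminoAcidChangeMatrix(
        observed=observed, bias=observed.sum() / space.max_changes_to_aa,
        bias_density=None, n_samples=None,
    )
    for scheme in ref.code.property_schemes:
        table = mc.physicochemical_changes(matrix, ref.code, scheme)
        assert np.isclose(table["percent"].sum(), 100.0)


def test_physicochemical_fraction_arithmetic(ref, space):
    # 117 changes of 460 in one class pair -> 25.4%
    aas = list(space.max_changes_to_aa.index)
    observed = pd.DataFrame(0, index=aas, columns=aas)
    observed.loc["A", "S"] = 117   # neutral apolar -> neutral polar
    observed.loc["D", "E"] = 460 - 117
    matrix = mc.AminoAcidChangeMatrix(observed, observed.sum(), None, None)
    table = mc.physicochemical_changes(matrix, ref.code, "acidity")
    row = table[
        (table.from_class == "neutral apolar") & (table.to_class == "neutral polar")
    ]
    assert np.isclose(row["percent"].iloc[0], 100 * 117 / 460, atol=0.05)


def test_unknown_scheme_rejected(ref, space):
    aas = list(space.max_changes_to_aa.index)
    matrix = mc.AminoAcidChangeMatrix(
        pd.DataFrame(0, index=aas, columns=aas), pd.Series(0, index=aas),
        None, None,
    )
    with pytest.raises(ValueError, match="unknown property scheme"):
        mc.physicochemical_changes(matrix, ref.code, "flavour")


def test_all_metrics_match_naive_reimplementation(space, small_calls):
    per_sample = small_calls.per_sample

    def units(v, ann):
        return [e.macrodivision for e in ann.genes] or ["intergenic"]

    naive = naive_diversity_volume(per_sample, units)
    table = mc.diversity_and_volume(small_calls.registry, "macrodivision")
    for unit, (d, vol) in naive.items():
        assert table.loc[unit, "diversity"] == d
        assert table.loc[unit, "volume"] == vol

    naive_counts = naive_definite_class_counts(per_sample)
    ours = mc.observed_definite_counts(small_calls.registry)
    assert dict(ours) == naive_counts

    naive_aa = naive_aa_change_counts(per_sample)
    matrix = mc.amino_acid_changes(small_calls.registry, space)
    for (src, dst), count in naive_aa.items():
        assert matrix.observed.loc[src, dst] == count
    assert matrix.observed.to_numpy().sum() == sum(naive_aa.values())
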