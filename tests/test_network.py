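"""Reaction table, parameter handling and the mass-action right-hand side."""

import numpy as np
import pytest

import nfkbse as nk
from nfkbse import network as net_mod
from nfkbse._kernels import get_kernel


@pytest.mark.parametrize(
    "column, symbol, expected",
    [
        ("fitted", "Aa", 0.1813),
        ("nominal", "Aa", 0.2),
        ("nominal", "C2", 0.0),
        ("fitted", "Kv", 5.0),
        ("fitted", "NFkB_total", 0.06),
        ("nominal", "K1", 0.0025),
        ("fitted", "K1", 0.003273),
        ("nominal", "Kprod", 2.5e-5),
    ],
)
def test_load_parameter_table_values(column, symbol, expected):
    params = nk.load_parameter_table(column=column)
    assert params[symbol] == pytest.approx(expected, rel=1e-12)


def test_parameter_table_complete_and_exact():
    params = nk.load_parameter_table(column="fitted")
    assert set(params) == set(net_mod.SYMBOLS)
    assert len(net_mod.SYMBOLS) == 71
    assert all(v >= 0 for v in params.values())


def test_load_rejects_bad_column_and_conflicting_symbols(tmp_path):
    with pytest.raises(ValueError):
        nk.load_parameter_table(column="typo")
    bad = tmp_path / "bad.tsv"
    src = (net_mod.importlib.resources.files("nfkbse.data") / "rate_constants.tsv").read_text()
    # corrupt one shared-symbol row far beyond the 0.5% agreement tolerance
    bad.write_text(src.replace(
        "IKKa_IkBa_NFkB -> IKKa + IkBa_NFkB\tDa\tb\t0.00125",
        "IKKa_IkBa_NFkB -> IKKa + IkBa_NFkB\tDa\tb\t0.5"))
    with pytest.raises(ValueError, match="Da"):
        nk.load_parameter_table(bad, column="nominal")


def test_parameter_table_round_trip(tmp_path, params_fitted):
    path = tmp_path / "params.tsv"
    nk.write_parameter_table(params_fitted, path)
    assert nk.load_parameter_table(path, column="fitted") == params_fitted


class TestKnockouts:
    def test_wild_type_is_identity(self, params_nominal):
        assert nk.apply_knockout(params_nominal, nk.Genotype.wild_type()) == params_nominal

    def test_a20_knockout_zeroes_both_synthesis_channels(self, params_nominal):
        ko = nk.apply_knockout(params_nominal, nk.Genotype.parse(["A20"]))
        assert ko["C1"] == 0.0 and ko["C2"] == 0.0
        changed = {s for s in ko if ko[s] != params_nominal[s]}
        assert changed <= {"C1", "C2"}

    def test_double_ikb_knockout(self, params_nominal):
        ko = nk.apply_knockout(params_nominal, nk.Genotype.parse(["IkBb", "IkBe"]))
        assert ko["Ub"] == ko["Ue"] == ko["Yb"] == ko["Ye"] == 0.0
        assert ko["Ua"] == params_nominal["Ua"]  # alpha untouched

    def test_input_not_mutated(self, params_nominal):
        before = dict(params_nominal)
        nk.apply_knockout(params_nominal, nk.Genotype.parse(["A20"]))
        assert dict(params_nominal) == before

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValueError, match="unknown knockout"):
            nk.Genotype.parse(["NotAGene"])


class TestDerivatives:
    def test_zero_state_only_zeroth_order_sources_fire(self, params_nominal):
        """At the all-zero state only the constant sources act: IKK
        production and the constitutive mRNA syntheses."""
        net = nk.get_network()
        d = net.derivatives(np.zeros(net.n_species), params_nominal, TR=1.0)
        sources = {"IKKn": "Kprod", "A20t": "C2",
                   "IkBat": "Ya", "IkBbt": "Yb", "IkBet": "Ye"}
        for name, sym in sources.items():
            assert d[net_mod.species_index(name)] == pytest.approx(params_nominal[sym])
        mask = np.ones(net.n_species, bool)
        for name in sources:
            mask[net_mod.species_index(name)] = False
        assert np.all(d[mask] == 0.0)

    def test_tr_zero_disables_ikk_activation(self, params_nominal):
        net = nk.get_network()
        rng = np.random.default_rng(0)
        s = rng.random(net.n_species) * 0.1
        d0 = net.derivatives(s, params_nominal, 0.0)
        d1 = net.derivatives(s, params_nominal, 1.0)
        diff = d1 - d0
        # only IKKn and IKKa move, by exactly K1*[IKKn]
        k1_flux = params_nominal["K1"] * s[net_mod.species_index("IKKn")]
        assert diff[net_mod.species_index("IKKn")] == pytest.approx(-k1_flux)
        assert diff[net_mod.species_index("IKKa")] == pytest.approx(k1_flux)
        others = [i for i in range(net.n_species)
                  if net.species[i] not in ("IKKn", "IKKa")]
        assert np.allclose(diff[others], 0.0)

    def test_tr_linearity_of_stimulated_flux(self, params_nominal):
        net = nk.get_network()
        s = np.random.default_rng(1).random(net.n_species) * 0.05
        d1 = net.derivatives(s, params_nominal, 0.7)
        d2 = net.derivatives(s, params_nominal, 1.4)
        k1_flux = params_nominal["K1"] * 0.7 * s[net_mod.species_index("IKKn")]
        expect = np.zeros(net.n_species)
        expect[net_mod.species_index("IKKn")] = -k1_flux
        expect[net_mod.species_index("IKKa")] = k1_flux
        assert np.allclose(d2 - d1, expect, atol=1e-15)

    @pytest.mark.parametrize("seed", range(5))
    def test_nfkb_conservation_of_rhs(self, params_fitted, seed):
        """No reaction creates or destroys NF-κB: the volume-weighted total
        has exactly zero time derivative for any state."""
        net = nk.get_network()
        s = np.random.default_rng(seed).random(net.n_species)
        d = net.derivatives(s, params_fitted, TR=1.0)
        w = net.nfkb_weights(params_fitted)
        scale = max(float(np.abs(w * d).sum()), 1e-30)
        assert abs(w @ d) <= 1e-12 * scale

    def test_negative_state_beyond_tolerance_rejected(self, params_nominal):
        net = nk.get_network()
        s = np.zeros(net.n_species)
        s[0] = -1e-6
        with pytest.raises(ValueError, match="negative concentration"):
            net.derivatives(s, params_nominal, 1.0)


def test_reaction_coverage_of_table_rows():
    """Every reaction row of the packaged table maps to implemented fluxes:
    grouped-species rows (shared Kdeg, Wα..ϵ) expand, constants do not."""
    net = nk.get_network()
    rows = net.table[~net.table["symbol"].isin(["Kv", "NFkB_total"])]
    assert len(rows) == 78
    assert net.n_reactions == 83  # Kdeg row -> 3, each W row -> 2
    covered = {r.table_row for r in net.reactions}
    assert covered == set(rows.index)
    by_sym = {}
    for r in net.reactions:
        by_sym[r.symbol] = by_sym.get(r.symbol, 0) + 1
    assert by_sym["Kdeg"] == 3
    assert by_sym["Wa"] == by_sym["Wb"] == by_sym["We"] == 2


def test_knockout_nullity_keeps_mrna_at_zero(params_nominal):
    """With IκBβ knocked out, its transcript has no source and stays 0."""
    ko = nk.apply_knockout(params_nominal, nk.Genotype.parse(["IkBb"]))
    traj = nk.simulate_response(ko, nk.StimulusProtocol(TR=1.0, t_stimulate_h=2.0))
    assert np.all(traj.series("IkBbt") == 0.0)


def test_compiled_kernel_matches_reference_rhs(params_fitted):
    """The code-generated numba RHS equals the numpy stoichiometry×flux
    reference to machine precision on random states."""
    net = nk.get_network()
    kern = get_kernel()
    k = params_fitted.as_array()
    rng = np.random.default_rng(42)
    for tr in (0.0, 1.0, 0.37):
        s = rng.random(net.n_species) * 0.2
        ref = net.derivatives(s, params_fitted, tr)
        out = np.empty(net.n_species)
        kern.rhs(s, k, tr, out)
        assert np.allclose(out, ref, rtol=1e-12, atol=1e-18)
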