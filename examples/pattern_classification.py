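"""Four-way dynamic-pattern taxonomy on synthetic and simulated signals.

Synthetic waveforms exercise the classifier independently of the ODE
model; the knockout comparison then shows how removing negative
regulators reshapes the pattern distribution.
"""

import nfkbse as nk
from nfkbse.signals import SyntheticSignalSpec, generate_synthetic_signal

print("synthetic waveforms:")
for family, kw in [
    ("sustained_sine", {}),
    ("damped_cosine", {"decay_h": 2.0}),
    ("saturating_exponential", {}),
    ("constant", {"baseline": 0.3}),
]:
    t, y = generate_synthetic_signal(SyntheticSignalSpec(family=family, **kw))
    print(f"  {family:24s} -> {nk.classify_series(t, y).value}")

params = nk.load_parameter_table(column="nominal")
protocol = nk.StimulusProtocol(TR=1.0, t_stimulate_h=10.0)
print("\nsimulated ensembles (100 cells each):")
for label, genes in [("wild type", []), ("A20 knockout", ["A20"]),
                     ("IkBb/IkBe knockout", ["IkBb", "IkBe"])]:
    ens = nk.simulate_ensemble(params, genotype=nk.Genotype.parse(genes),
                               protocol=protocol, n=100, chi=0.3, seed=7)
    fractions = nk.pattern_distribution(nk.ensemble_features(ens)["pattern"])
    summary = ", ".join(f"{k.split('_')[0]} {100 * v:.0f}%"
                        for k, v in fractions.items() if v > 0)
    print(f"  {label:20s} {summary}")
# Removing A20 abolishes oscillations (single-peaked responses); removing the
# IκBβ/ϵ isoforms leaves the fast IκBα feedback loop in charge and the
# responses more oscillatory.
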