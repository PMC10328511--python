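"""The plasticity experiment: locomotion modulation index before/after.

Simulates a small closed-loop + optogenetic pairing arm and a control
arm, measures each neuron's locomotion modulation index
LMI = (R_loco - R_stat)/sqrt(R_loco^2 + R_stat^2) for both flow
directions before and after the pairing epoch, and tests the change
with the hierarchical (site -> neuron) bootstrap.  Only nasotemporal
responses in the paired arm should lose their locomotion gain.
"""

from mismatch2p import pipeline, synth

config = synth.SessionConfig(frame_rate=15.0, duration=300.0)
pop = synth.sample_v1_population(n_mice=3, n_sites_per_mouse=2,
                                 n_neurons_per_site=20, seed=5)

for protocol in ("closed_loop_opto", "control"):
    exp = synth.simulate_v1_experiment(config, pop, protocol, "high",
                                       closed_duration=240.0, open_duration=480.0,
                                       seed=6)
    res = pipeline.analyze_v1_experiment(exp, n_boot=2000, seed=7, classify=False)
    print(f"\n{protocol} (plasticity applied: {exp.plasticity_applied})")
    for direction, d in res["delta_lmi"].items():
        print(f"  {direction}: LMI {d['mean_lmi_pre']:+.3f} -> {d['mean_lmi_post']:+.3f}, "
              f"dLMI = {d['mean_dlmi']:+.3f} (two-sided p = {d['p_two_sided']:.4g}, "
              f"n = {d['n_neurons']} neurons)")
    sb = res["speed_bin"]
    print(f"  post-epoch LMI vs speed-bin slope: {sb['slope']:+.4f} "
          f"(p negative = {sb['p_negative']:.4g})")

print("\nonly the paired nasotemporal responses show a large LMI drop; at this")
print("demonstration scale (6 sites) null-arm p-values fluctuate — the test")
print("suite runs the experiment at its full 24-site design.")
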