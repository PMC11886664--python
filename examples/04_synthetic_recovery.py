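"""Parameter-recovery experiment on synthetic molecules with known bci.

Generates random connected molecules whose charges follow the forward
MMFF94 rule from a known increment table plus Gaussian noise, refits each
one, and reports the bias and RMSE of the recovered increments.
"""

from bcisolve import GeneratorConfig, recovery_experiment

for noise in (0.0, 0.05):
    cfg = GeneratorConfig(n_atoms=8, type_alphabet=("A", "B", "C"),
                          noise_sd=noise, seed=0)
    report = recovery_experiment(cfg, n_structures=200)
    print(f"noise sd {noise} e, {report.n_structures} structures:")
    for key, entry in report.per_key.items():
        print(f"  {key}: true {entry.true:+.4f}  mean {entry.mean:+.4f}  "
              f"bias {entry.bias:+.5f}  rmse {entry.rmse:.5f}  (n={entry.n})")

# With no noise the fit is exact to numerical precision. With 0.05 e of
# per-atom noise the estimates scatter (rmse ~ a few hundredths of e) but
# stay unbiased, as expected for unweighted least squares under zero-mean
# noise.
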