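"""Full processing chain: noisy speech with and without the denoiser.

Runs the synthetic-vowel source through the chain at 0 dB Gaussian
noise, once with the decision-directed spectral denoiser and once
without, and compares output SNR and envelope fidelity to the clean run.
"""

import numpy as np

from cisim import ScenarioConfig, run_scenario

clean = run_scenario(ScenarioConfig(source="vowel", seed=1, duration=5.0))
noisy = run_scenario(ScenarioConfig(source="vowel", noise="gaussian",
                                    snr_db=0.0, seed=1, duration=5.0))
denoised = run_scenario(ScenarioConfig(source="vowel", noise="gaussian",
                                       snr_db=0.0, denoise=True, seed=1,
                                       duration=5.0))


def mean_corr(run):
    return np.mean([
        np.corrcoef(run.envelopes[c].samples, clean.envelopes[c].samples)[0, 1]
        for c in range(8)
    ])


print(f"input SNR:                {denoised.metrics['snr_in_db']:.2f} dB")
print(f"output SNR after denoise: {denoised.metrics['snr_out_db']:.2f} dB")
print(f"envelope correlation with clean run:")
print(f"  without denoise: {mean_corr(noisy):.3f}")
print(f"  with denoise:    {mean_corr(denoised):.3f}")
print(f"pulse-train range: [{denoised.pulses.trains.min():.2f}, "
      f"{denoised.pulses.trains.max():.2f}] (full scale +/-6)")
print("\nThe denoiser recovers several dB of SNR and the per-channel")
print("envelopes move closer to what the clean signal would have produced,")
print("i.e. the stimulation pattern the implant delivers is less corrupted.")
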