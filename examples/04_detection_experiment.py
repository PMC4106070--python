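"""A reduced end-to-end seizure-detection experiment.

Generates a labeled synthetic dataset, selects the band, extracts and scales
cross-power features, pretrains the stacked autoencoder with the correntropy
loss, trains the softmax head, fine-tunes jointly, and reports held-out
sensitivity/specificity over three initialization trials.  (The full-size
protocol — 1000 + 4000 segments, 750 + 750 training, ten trials — is what
``rsae run-all`` and scripts/acceptance.py execute.)
"""

from rsae import ExperimentConfig, SynthConfig, run_experiment
from rsae.autoencoder import AEConfig

config = ExperimentConfig(
    synth=SynthConfig(seed=21),
    n_seizure=150, n_nonseizure=300, n_train_per_class=100,
    hidden_units=30, q=6,
    ae=AEConfig(loss_type="mcc", max_iter=200), finetune_max_iter=200,
    n_trials=3, seed=21,
)

result = run_experiment(config)
print(result.summary())
# Sensitivity is the fraction of held-out seizure windows flagged, specificity
# the fraction of nonseizure windows passed; "pre-FT" rows use the pretrained
# features with only the softmax head trained, before joint fine-tuning.
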