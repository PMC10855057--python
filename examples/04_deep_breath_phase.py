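"""Train the CNN-LSTM breath-phase classifier on a small synthetic set.

Each 30 Hz respiratory signal is z-scored, clipped to +/-2, and labelled
per sample (above zero = inhalation).  The network (conv1d -> max pool ->
ReLU -> LSTM -> per-timestep softmax) learns the labelling; RR follows
from counting inhalation onsets in the predicted labels.
"""
import numpy as np

from respyre import (ModelConfig, build_model, label_breath_phase,
                     pool_labels, predict_labels, rr_from_labels,
                     split_dataset, train_model)
from respyre.pipeline import make_synthetic_resp_dataset

config = ModelConfig(window_samples=210, pool_size=2, epochs=10, seed=0)
windows, reference_rr = make_synthetic_resp_dataset(n_subjects=60, seed=0)
train, val, test = split_dataset(windows, config, by="subject")
print(f"windows: {train.n_windows} train / {val.n_windows} val / "
      f"{test.n_windows} test (subject-disjoint)")


def as_xy(ws):
    return ws.windows, pool_labels(label_breath_phase(ws.windows), config)


model = train_model(build_model(config), as_xy(train), as_xy(val), config)
print(f"best validation loss {model.best_val_loss:.3f} at epoch {model.best_epoch}")

labels = predict_labels(model, test.windows)
reference = pool_labels(label_breath_phase(test.windows), config)
print(f"held-out label accuracy: {(labels == reference).mean():.3f}")

# RR for one test minute: concatenate its 8 windows' predicted labels
subject = test.subject_ids[0]
idx = [i for i in range(test.n_windows) if test.subject_ids[i] == subject]
idx.sort(key=lambda i: test.source_intervals[i][0])
minute_labels = np.concatenate([labels[i] for i in idx])
estimate = rr_from_labels(minute_labels, len(idx) * 7.0)
print(f"subject {subject}: estimated RR {estimate.value:.2f}, "
      f"reference {reference_rr[(subject, 0)]:.2f} breaths/min")
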