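"""Helpers shared by the test modules (kept out of conftest fixtures)."""

import numpy as np

import wavefusion as wf


def random_tensor_dataset(n_subjects=2, per_class=6, n_leads=3,
                          shape=(39, 11), seed=0, class_shift=0.0):
    """A TensorDataset of nonnegative random spectrogram tensors.

    ``class_shift`` adds a constant to class-1 tensors so the classes are
    linearly separable when a test needs learnable structure.
    """
    r = np.random.default_rng(seed)
    X, y1, y2 = [], [], []
    for subj in range(1, n_subjects + 1):
        for cls in (0, 1):
            x = r.random((per_class, n_leads) + shape) + cls * class_shift
            X.append(x)
            y1.extend([cls] * per_class)
            y2.extend([subj] * per_class)
    names = tuple(f"L{i}" for i in range(n_leads))
    return wf.TensorDataset(np.concatenate(X), np.array(y1), np.array(y2),
                            names, np.arange(shape[0]), np.arange(shape[1]))


def big_labeled_dataset(n_subjects=3, per_class=30):
    """A label-rich dataset with tiny tensors for sampler tests."""
    return random_tensor_dataset(n_subjects=n_subjects, per_class=per_class,
                                 n_leads=1, shape=(2, 2), seed=3)
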