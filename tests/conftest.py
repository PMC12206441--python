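import numpy as np
import pytest

from kirquant.image_quant import mask_iou


def best_match_iou(pred_labels: np.ndarray, true_mask: np.ndarray) -> float:
    """IoU of the predicted label best matching a true object mask."""
    best = 0.0
    for lab in np.unique(pred_labels[pred_labels > 0]):
        best = max(best, mask_iou(pred_labels == lab, true_mask))
    return best


@pytest.fixture
def noiseless_field():
    """Five non-overlapping cells with nucleoli, no noise."""
    from kirquant.synthetic import cell_field_preset, simulate_cell_field

    params = cell_field_preset("WT", seed=3, n_cells=5, noise_gaussian_sd=0.0)
    return simulate_cell_field(params)
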