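import numpy as np
import pytest
from skimage.draw import circle_perimeter
from skimage.morphology import dilation, disk

from vasomech import waviness


@pytest.fixture
def half_circle_skeleton():
    """1-px skeleton of a digitized half circle of radius 80 px.

    Ground truth chord/arc = 2r / (pi r) = 2/pi.
    """
    size, radius = 220, 80
    rr, cc = circle_perimeter(110, 110, radius)
    keep = rr <= 110
    mask = np.zeros((size, size), dtype=bool)
    mask[rr[keep], cc[keep]] = True
    mask = dilation(mask, disk(2))
    return waviness.skeletonize_and_prune(mask, min_component_px=10)


def straight_line_mask(length=180, thickness=5, shape=(64, 200)):
    mask = np.zeros(shape, dtype=bool)
    r = shape[0] // 2
    mask[r - thickness // 2 : r + thickness // 2 + 1, 10 : 10 + length] = True
    return mask


def kapur_bruteforce(counts):
    """Exhaustive-search maximum-entropy split of a histogram.

    Independent oracle: for every candidate split t, compute the Shannon
    entropies of the normalized class histograms {0..t} and {t+1..} from
    first principles and return the t maximizing their sum (lowest t wins
    ties).
    """
    p = np.asarray(counts, dtype=float)
    p = p / p.sum()
    best_h, best_t = -np.inf, None
    for t in range(len(p) - 1):
        lo, hi = p[: t + 1], p[t + 1 :]
        w0, w1 = lo.sum(), hi.sum()
        if w0 <= 0 or w1 <= 0:
            continue
        q0 = lo[lo > 0] / w0
        q1 = hi[hi > 0] / w1
        h = -(q0 * np.log(q0)).sum() - (q1 * np.log(q1)).sum()
        if h > best_h + 1e-12:
            best_h, best_t = h, t
    return best_t
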