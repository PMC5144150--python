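import numpy as np
import pytest

from chromodyn.segmentation import segment_nuclei
from chromodyn.synthetic import SceneParams, generate_nucleus_image


@pytest.fixture(scope="session")
def noiseless_scene():
    """One nucleus, 15 identical well-separated spots, no noise."""
    params = SceneParams(
        chromocenters_mean=15, chromocenters_sd=0,
        radius_mean_px=5, radius_sd_px=0,
        noise_sd=0, seed=3,
    )
    return generate_nucleus_image(params)


@pytest.fixture(scope="session")
def noiseless_nuclei(noiseless_scene):
    return segment_nuclei(noiseless_scene.dapi, min_nucleus_area=1000)


def flood_fill_oracle(img, markers, mask):
    """Exhaustive flood-fill-by-descending-threshold labeling.

    Pixels are visited in descending intensity order (repeatedly, until no
    pixel can be assigned); an unlabeled pixel takes the label of its
    brightest already-labeled 4-neighbor.  Independent of the heap-based
    watershed it is used to check.
    """
    labels = markers.copy()
    order = np.argsort(-img[mask], kind="stable")
    pending = [tuple(c) for c in np.argwhere(mask)[order]]
    changed = True
    while pending and changed:
        changed = False
        remaining = []
        for r, c in pending:
            if labels[r, c]:
                changed = True
                continue
            best, best_val = 0, -np.inf
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if (0 <= rr < img.shape[0] and 0 <= cc < img.shape[1]
                        and labels[rr, cc] and img[rr, cc] > best_val):
                    best, best_val = labels[rr, cc], img[rr, cc]
            if best:
                labels[r, c] = best
                changed = True
            else:
                remaining.append((r, c))
        pending = remaining
    return labels
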