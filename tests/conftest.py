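import warnings

import numpy as np
import pytest

from her2ish.pipeline import analyze_roi_image
from her2ish.profiles import CaseProfile
from her2ish.synth import render_roi


@pytest.fixture(scope="session")
def clean_roi():
    """One clean rendered ROI (0.2 um/px) with its sidecar and analysis."""
    profile = CaseProfile(4.0, 2.2, dispersion=0.1)
    image, sidecar = render_roi(profile, 600, 600, 0.2, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        analysis = analyze_roi_image(image, 0.2)
    return image, sidecar, analysis


def match_points(truth: np.ndarray, detected: np.ndarray, tol):
    """Hungarian matching; returns boolean per-truth matched mask."""
    from scipy.optimize import linear_sum_assignment

    if len(truth) == 0 or len(detected) == 0:
        return np.zeros(len(truth), dtype=bool), np.array([], dtype=int)
    d = np.linalg.norm(truth[:, None, :] - detected[None, :, :], axis=-1)
    ri, ci = linear_sum_assignment(d)
    tol = np.asarray(tol)
    tol_r = tol[ri] if tol.ndim else tol
    ok = d[ri, ci] <= tol_r
    matched = np.zeros(len(truth), dtype=bool)
    matched[ri[ok]] = True
    return matched, ci[ok]
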