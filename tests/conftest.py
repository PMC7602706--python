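import numpy as np
import pytest

from windfa import CohortSpec, generate_cohort


def naive_fluctuation(profile, scales, order=1):
    """Independent direct DFA fluctuation function: explicit loops,
    explicit polynomial fit per segment."""
    profile = np.asarray(profile, dtype=float)
    out = []
    for n in scales:
        n = int(n)
        n_seg = len(profile) // n
        ss = 0.0
        t = np.arange(n, dtype=float)
        for i in range(n_seg):
            seg = profile[i * n:(i + 1) * n]
            if order == 0:
                trend = np.full(n, seg.mean())
            else:
                coef = np.polyfit(t, seg, order)
                trend = np.polyval(coef, t)
            ss += np.sum((seg - trend) ** 2)
        out.append(np.sqrt(ss / (n_seg * n)))
    return np.array(out)


def ols_slope(x, y):
    """Closed-form OLS slope: sum((x-mx)(y-my)) / sum((x-mx)^2)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    return float(np.sum(xc * (y - y.mean())) / np.sum(xc ** 2))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort shared by pipeline-level tests."""
    spec = CohortSpec(n_subjects=3, trials_per_hand=6, keep_per_hand=4,
                      channels=("C3", "C4", "Cz"), seed=11)
    return spec, generate_cohort(spec)
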