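import numpy as np
import pytest

from critspeed.models import CSParameters, SubjectTrials, TrialObservation


def make_noiseless_subject(cs=4.0, d_prime=200.0, speeds=(4.5, 5.0, 5.5, 6.0), sid="S01"):
    """Trials generated exactly from the hyperbolic model (no noise)."""
    trials = tuple(
        TrialObservation(speed=s, time_to_exhaustion=d_prime / (s - cs)) for s in speeds
    )
    return SubjectTrials(subject_id=sid, trials=trials)


def make_subject_from_arrays(speeds, times, sid="S01"):
    trials = tuple(
        TrialObservation(speed=float(s), time_to_exhaustion=float(t))
        for s, t in zip(speeds, times)
    )
    return SubjectTrials(subject_id=sid, trials=trials)


def wls_linear_oracle(X, y, w=None):
    """Closed-form (weighted) normal-equations solution beta = (X'WX)^-1 X'Wy.

    Independent of the Levenberg-Marquardt path: pure linear algebra.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.ones(len(y)) if w is None else np.asarray(w, float)
    XtW = X.T * w
    return np.linalg.solve(XtW @ X, XtW @ y)


def ols_line_se_oracle(x, y):
    """Textbook simple-linear-regression SEs of slope and intercept."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    s2 = np.sum(resid**2) / (n - 2)
    sxx = np.sum((x - x.mean()) ** 2)
    se_slope = np.sqrt(s2 / sxx)
    se_intercept = np.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx))
    return slope, intercept, se_slope, se_intercept


@pytest.fixture
def noiseless_subject():
    return make_noiseless_subject()


@pytest.fixture
def params():
    return CSParameters(cs=4.0, d_prime=200.0)
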