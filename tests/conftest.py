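import numpy as np
import pytest

from t1mt.meta_analysis import GlobalMTFit, information_criteria
from t1mt.sequences import literature_roster
from t1mt.spin_models import WM_3T_FIT
from t1mt.synthetic_data import RosterSpec, generate_roster


@pytest.fixture(scope="session")
def wm_params():
    """The fitted white-matter two-pool parameter set."""
    return WM_3T_FIT


@pytest.fixture(scope="session")
def roster_protocols():
    return literature_roster()


@pytest.fixture(scope="session")
def replicate_study():
    """Recovery / model-selection study: 100 synthetic 25-method rosters
    (ground truth = the fitted white-matter set, observation noise 0.02 s),
    each fitted with the free-T1s and tied-T1s generalized Bloch models and
    the mono-exponential baseline.

    This is the expensive shared fixture behind the parameter-recovery and
    model-selection tests; ~6 s per replicate.
    """
    rows = []
    for i in range(100):
        seed = 1000 + i
        obs = generate_roster(RosterSpec(seed=seed))
        X = [o.method_id for o in obs]
        y = [o.observed_t1 for o in obs]
        unc = GlobalMTFit().fit(X, y)
        tied = GlobalMTFit(tie_t1s=True).fit(X, y)
        mono = GlobalMTFit(model="mono").fit(X, y)
        da_u, db_u = information_criteria(unc.rss_, mono.rss_, len(y), 3, 1)
        da_t, db_t = information_criteria(tied.rss_, mono.rss_, len(y), 2, 1)
        rows.append(
            dict(
                seed=seed,
                m0s=unc.params_.m0s,
                t1f=unc.params_.t1f,
                t1s=unc.params_.t1s,
                rss_unconstrained=unc.rss_,
                rss_tied=tied.rss_,
                rss_mono=mono.rss_,
                delta_aic_unconstrained=da_u,
                delta_bic_unconstrained=db_u,
                delta_aic_tied=da_t,
                delta_bic_tied=db_t,
            )
        )
    return rows


_MAGIC_ANGLE = np.arccos(np.sqrt(1.0 / 3.0))


def angular_quadrature_lineshape(offset_hz, t2s):
    """Adaptive quadrature of the super-Lorentzian over the orientation angle
    (independent oracle for the fixed Gauss-Legendre path)."""
    from scipy.integrate import quad

    w = 2.0 * np.pi * offset_hz * t2s

    def kernel(th):
        u = abs(3.0 * np.cos(th) ** 2 - 1.0)
        return (
            np.sqrt(2.0 / np.pi) * t2s * np.sin(th) / u * np.exp(-2.0 * (w / u) ** 2)
        )

    val, _ = quad(
        kernel, 0.0, np.pi / 2, points=[_MAGIC_ANGLE], limit=500, epsrel=1e-11
    )
    return float(val)


def angular_quadrature_fid(t, t2s):
    from scipy.integrate import quad

    def kernel(th):
        u2 = (3.0 * np.cos(th) ** 2 - 1.0) ** 2
        return np.sin(th) * np.exp(-u2 * (t / t2s) ** 2 / 8.0)

    val, _ = quad(
        kernel, 0.0, np.pi / 2, points=[_MAGIC_ANGLE], limit=500, epsrel=1e-12
    )
    return float(val)
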