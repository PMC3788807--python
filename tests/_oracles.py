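"""Independent numerical-convolution oracles for the kinetic closed forms.

Each oracle evaluates the defining convolution

    dM(t) = 2 * M0b * f * integral_0^t c(s) * r(t - s) * m(t - s) ds

by trapezoidal quadrature on a grid of at most 1 ms spacing.  The
integrand is only piecewise smooth (boxcar delivery, boxcar pre-capillary
residue), so the integral is taken over the support of each smooth piece
rather than blindly across the discontinuities; within a piece the
trapezoid rule is second-order accurate.  Nothing here touches the
closed-form implementations under test.
"""

import numpy as np


def _trapz_segment(fn, lo: float, hi: float, h: float = 1e-3) -> float:
    if hi <= lo:
        return 0.0
    n = max(2, int(np.ceil((hi - lo) / h)) + 1)
    s = np.linspace(lo, hi, n)
    return float(np.trapezoid(fn(s), s))


def numeric_single_stage(ti, BAT, CBF, T1t, M0b, constants, tau=None):
    """Brute-force single-stage dM: exponential residue, T1t relaxation."""
    tau = constants.tau if tau is None else tau
    f = CBF / 6000.0
    k = f / constants.lambda_bp + 1.0 / T1t
    out = []
    for t in np.atleast_1d(np.asarray(ti, dtype=float)):
        integrand = lambda s, t=t: constants.alpha * np.exp(-s / constants.T1b) * np.exp(-k * (t - s))
        out.append(2.0 * M0b * f * _trapz_segment(integrand, BAT, min(t, BAT + tau)))
    return np.array(out)


def numeric_pre_capillary(ti, BAT, CBF, pcTT, M0b, constants, tau=None):
    """Brute-force pre-capillary dM: boxcar residue of length pcTT, T1b relaxation.

    The residue restricts the delivery window to s > t - pcTT.
    """
    tau = constants.tau if tau is None else tau
    f = CBF / 6000.0
    out = []
    for t in np.atleast_1d(np.asarray(ti, dtype=float)):
        lo = max(BAT, t - pcTT)
        hi = min(t, BAT + tau)
        integrand = lambda s, t=t: (
            constants.alpha * np.exp(-s / constants.T1b) * np.exp(-(t - s) / constants.T1b)
        )
        out.append(2.0 * M0b * f * _trapz_segment(integrand, lo, hi))
    return np.array(out)


def numeric_two_stage(ti, BAT, CBF, pcTT, f_pc, BAT_c, T1t, M0b, constants):
    """Brute-force two-stage dM: weighted sum of the two component oracles."""
    pc = numeric_pre_capillary(ti, BAT, CBF, pcTT, M0b, constants)
    cap = numeric_single_stage(ti, BAT_c, CBF, T1t, M0b, constants)
    return f_pc * pc + (1.0 - f_pc) * cap
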