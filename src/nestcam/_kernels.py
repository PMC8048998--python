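"""Numba kernels for the 3-state nest hidden Markov model.

Latent state z_t in {0, 1, 2} is the number of surviving eggs/chicks in a
nest; z_1 = 2 (two-egg clutch), z_t | z_{t-1} ~ Binomial(z_{t-1}, phi), and
the observed count y_t | z_t ~ Binomial(z_t, p_t) on days with data
(y_t = -1 marks a missing day and contributes no factor).

``forward_logliks`` marginalizes z exactly by the scaled forward recursion;
``sample_latent_totals`` recovers latent-state draws by forward filtering /
backward sampling (FFBS) and accumulates the colony-level total trajectory
Z_t per posterior draw.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def forward_logliks(y, phi, p):
    """Marginal log-likelihood per nest.

    Parameters
    ----------
    y : (T, N) int64, values in {0,1,2}, -1 = missing
    phi : (N,) daily survival probability per nest
    p : (T, N) daily detection probability per nest

    Returns
    -------
    (N,) float64 log-likelihoods (-inf where the data are impossible).
    """
    T, N = y.shape
    out = np.empty(N)
    for n in range(N):
        ph = phi[n]
        t22 = ph * ph
        t21 = 2.0 * ph * (1.0 - ph)
        t20 = (1.0 - ph) * (1.0 - ph)
        t11 = ph
        t10 = 1.0 - ph
        a0 = 0.0
        a1 = 0.0
        a2 = 1.0
        ll = 0.0
        dead = False
        for t in range(T):
            if t > 0:
                b0 = a0 + a1 * t10 + a2 * t20
                b1 = a1 * t11 + a2 * t21
                b2 = a2 * t22
                a0, a1, a2 = b0, b1, b2
            yt = y[t, n]
            if yt >= 0:
                pt = p[t, n]
                q = 1.0 - pt
                if yt == 0:
                    a1 *= q
                    a2 *= q * q
                elif yt == 1:
                    a0 = 0.0
                    a1 *= pt
                    a2 *= 2.0 * pt * q
                else:
                    a0 = 0.0
                    a1 = 0.0
                    a2 *= pt * pt
            s = a0 + a1 + a2
            if s <= 0.0:
                out[n] = -np.inf
                dead = True
                break
            ll += np.log(s)
            a0 /= s
            a1 /= s
            a2 /= s
        if not dead:
            out[n] = ll
    return out


@njit(cache=False)
def sample_latent_totals(y, x, phi_d, mu_p_d, beta_d, nu_d, seed):
    """FFBS draws of the total-chick trajectory Z_t = sum_i z_{t,i}.

    Parameters
    ----------
    y : (T, N) int64 observations for one site/year (-1 missing)
    x : (T,) detection time covariate
    phi_d : (D,) survival draws
    mu_p_d, beta_d : (D,) detection intercept / slope draws
    nu_d : (D, N) nest detection offset draws
    seed : RNG seed for the backward sampling

    Returns
    -------
    (D, T) int64 total chicks alive per draw and day.
    """
    np.random.seed(seed)
    D, N = nu_d.shape
    T = y.shape[0]
    Z = np.zeros((D, T), dtype=np.int64)
    alpha = np.empty((T, 3))
    for d in range(D):
        ph = phi_d[d]
        t22 = ph * ph
        t21 = 2.0 * ph * (1.0 - ph)
        t20 = (1.0 - ph) * (1.0 - ph)
        t11 = ph
        t10 = 1.0 - ph
        for n in range(N):
            # forward filter
            a0 = 0.0
            a1 = 0.0
            a2 = 1.0
            for t in range(T):
                if t > 0:
                    b0 = a0 + a1 * t10 + a2 * t20
                    b1 = a1 * t11 + a2 * t21
                    b2 = a2 * t22
                    a0, a1, a2 = b0, b1, b2
                yt = y[t, n]
                if yt >= 0:
                    pt = 1.0 / (1.0 + np.exp(-(mu_p_d[d] + nu_d[d, n] + beta_d[d] * x[t])))
                    q = 1.0 - pt
                    if yt == 0:
                        a1 *= q
                        a2 *= q * q
                    elif yt == 1:
                        a0 = 0.0
                        a1 *= pt
                        a2 *= 2.0 * pt * q
                    else:
                        a0 = 0.0
                        a1 = 0.0
                        a2 *= pt * pt
                s = a0 + a1 + a2
                a0 /= s
                a1 /= s
                a2 /= s
                alpha[t, 0] = a0
                alpha[t, 1] = a1
                alpha[t, 2] = a2
            # backward sample
            u = np.random.random()
            if u < alpha[T - 1, 0]:
                z = 0
            elif u < alpha[T - 1, 0] + alpha[T - 1, 1]:
                z = 1
            else:
                z = 2
            Z[d, T - 1] += z
            for t in range(T - 2, -1, -1):
                if z == 0:
                    w0 = alpha[t, 0]
                    w1 = alpha[t, 1] * t10
                    w2 = alpha[t, 2] * t20
                elif z == 1:
                    w0 = 0.0
                    w1 = alpha[t, 1] * t11
                    w2 = alpha[t, 2] * t21
                else:
                    w0 = 0.0
                    w1 = 0.0
                    w2 = alpha[t, 2] * t22
                s = w0 + w1 + w2
                u = np.random.random() * s
                if u < w0:
                    z = 0
                elif u < w0 + w1:
                    z = 1
                else:
                    z = 2
                Z[d, t] += z
    return Z
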