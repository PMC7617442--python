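"""Independent oracles shared by unit and acceptance tests.

The grid check below verifies that each closed-form full conditional used
by the Gibbs sampler is proportional to the joint log-density restricted to
its block: the difference log_joint(x) − log q(x) must be constant in x.
"""

import numpy as np

import sesindex as si
from sesindex.sampler import (conditional_alpha, conditional_alpha_star,
                              conditional_beta, conditional_theta,
                              conditional_ystar)


def _normal_logpdf(x, mean, var):
    return -0.5 * (x - mean) ** 2 / var - 0.5 * np.log(2 * np.pi * var)


def _const_deviation(vals):
    vals = np.asarray(vals)
    return float(np.max(np.abs(vals - vals.mean())))


def conditional_gridcheck(data, adjacency, spec, state, n_grid: int = 20):
    """Max deviation-from-constant of log_joint − log q over every
    closed-form conditional block; exact conditionals give ~0."""
    adj = adjacency if (spec.spatial_theta or spec.icar_theta) else None
    st = state.copy()
    devs = {}

    def lj():
        return si.log_joint(st, data, spec, adj)

    dich = np.asarray(spec.is_dichotomous)
    dich_idx = np.nonzero(dich)[0]

    # y* blocks (truncated normal, unit variance, sign fixed by the data)
    if dich_idx.size:
        eta, sgn = conditional_ystar(st, data, spec)
        h, j = 0, 0  # first household, first dichotomous variable
        k = dich_idx[j]
        lo, hi = (0.01, 3.0) if sgn[h, j] > 0 else (-3.0, -0.01)
        grid = np.linspace(lo, hi, n_grid)
        keep = st.ystar[h, k]
        vals = []
        for x in grid:
            st.ystar[h, k] = x
            vals.append(lj() - _normal_logpdf(x, eta[h, j], 1.0))
        st.ystar[h, k] = keep
        devs["ystar"] = _const_deviation(vals)

    # alpha block
    if dich_idx.size:
        mean_a, var_a = conditional_alpha(st, data, spec)
        k = dich_idx[0]
        grid = np.linspace(-2.5, 2.5, n_grid)
        vals = []
        if spec.hierarchical_alpha:
            keep = st.alpha[0, k]
            for x in grid:
                st.alpha[0, k] = x
                vals.append(lj() - _normal_logpdf(x, mean_a[0, 0],
                                                  var_a[0, 0]))
            st.alpha[0, k] = keep
        else:
            keep = st.alpha[:, k].copy()
            for x in grid:
                st.alpha[:, k] = x
                vals.append(lj() - _normal_logpdf(x, mean_a[0], var_a[0]))
            st.alpha[:, k] = keep
        devs["alpha"] = _const_deviation(vals)

    # alpha_star block
    if dich_idx.size and spec.hierarchical_alpha:
        mean_s, var_s = conditional_alpha_star(st, data, spec)
        k = dich_idx[0]
        keep = st.alpha_star[k]
        grid = np.linspace(-2.5, 2.5, n_grid)
        vals = []
        for x in grid:
            st.alpha_star[k] = x
            vals.append(lj() - _normal_logpdf(x, mean_s[0], var_s))
        st.alpha_star[k] = keep
        devs["alpha_star"] = _const_deviation(vals)

    # beta block (positive half-line)
    mean_b, var_b = conditional_beta(st, data, spec)
    keep = st.beta[0]
    grid = np.linspace(0.05, 3.0, n_grid)
    vals = []
    for x in grid:
        st.beta[0] = x
        vals.append(lj() - _normal_logpdf(x, mean_b[0], var_b[0]))
    st.beta[0] = keep
    devs["beta"] = _const_deviation(vals)

    # theta block
    mean_t, var_t = conditional_theta(st, data, spec, adjacency)
    keep = st.theta[0]
    grid = np.linspace(-2.5, 2.5, n_grid)
    vals = []
    for x in grid:
        st.theta[0] = x
        vals.append(lj() - _normal_logpdf(x, mean_t[0], var_t[0]))
    st.theta[0] = keep
    devs["theta"] = _const_deviation(vals)

    return devs
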