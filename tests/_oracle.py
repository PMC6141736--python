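"""Independent brute-force oracles for the test suite.

The CNI oracle evaluates the product-binomial log-likelihood on an
exhaustive parameter grid (written from the tree equations directly, not
via the package's likelihood code) and refines around the coarse argmax
with a second, finer exhaustive grid.  It shares no code path with the
quasi-Newton fitter it is used to check.
"""

from __future__ import annotations

import numpy as np

COARSE = np.linspace(0.0, 1.0, 101)


def _cube_loglik(n_action, n_inaction, c_grid, n_grid, i_grid) -> np.ndarray:
    """Log-likelihood over the full (C, N, I) grid, shape (|C|,|N|,|I|)."""
    C = c_grid[:, None, None]
    N = n_grid[None, :, None]
    I = i_grid[None, None, :]
    q = (1 - C) * (1 - N) * (1 - I)
    cell_probs = [C + q, q + np.zeros_like(C * N * I), C + (1 - C) * N + q,
                  (1 - C) * N + q]
    ll = np.zeros(np.broadcast_shapes(C.shape, N.shape, I.shape))
    for k, p in enumerate(cell_probs):
        pc = np.clip(p, 1e-12, 1 - 1e-12)
        ll = ll + n_action[k] * np.log(pc) + n_inaction[k] * np.log1p(-pc)
    return ll


def _fine_axis(center: float, half: float = 0.015, points: int = 121) -> np.ndarray:
    return np.linspace(max(0.0, center - half), min(1.0, center + half), points)


def grid_fit(counts, fixed: dict[str, float] | None = None):
    """Two-stage exhaustive grid maximization; returns ((C,N,I), loglik).

    ``fixed`` pins parameters ("C"/"N"/"I") at given values.
    """
    fixed = fixed or {}
    axes = []
    for name in ("C", "N", "I"):
        axes.append(np.array([fixed[name]]) if name in fixed else COARSE)
    ll = _cube_loglik(counts.n_action, counts.n_inaction, *axes)
    idx = np.unravel_index(np.argmax(ll), ll.shape)
    coarse = [float(ax[i]) for ax, i in zip(axes, idx)]

    fine_axes = [
        np.array([fixed[name]]) if name in fixed else _fine_axis(coarse[j])
        for j, name in enumerate(("C", "N", "I"))
    ]
    ll2 = _cube_loglik(counts.n_action, counts.n_inaction, *fine_axes)
    idx2 = np.unravel_index(np.argmax(ll2), ll2.shape)
    best = tuple(float(ax[i]) for ax, i in zip(fine_axes, idx2))
    return best, float(ll2[idx2])


def grid_equality_fit(counts_a, counts_b, parameter: str):
    """Max joint loglik with one parameter shared across two groups.

    Coarse pass reduces each group's 101³ cube over the non-shared axes,
    then refines the shared value and each group's free parameters with
    fine exhaustive grids.
    """
    j = ("C", "N", "I").index(parameter)
    cubes = [
        _cube_loglik(c.n_action, c.n_inaction, COARSE, COARSE, COARSE)
        for c in (counts_a, counts_b)
    ]
    others = tuple(k for k in range(3) if k != j)
    vecs = [cube.max(axis=others) for cube in cubes]
    shared_idx = int(np.argmax(vecs[0] + vecs[1]))
    shared0 = float(COARSE[shared_idx])

    # coarse per-group argmax of the free parameters at the shared value
    frees0 = []
    for cube in cubes:
        sl = np.take(cube, shared_idx, axis=j)
        frees0.append(np.unravel_index(np.argmax(sl), sl.shape))

    shared_axis = _fine_axis(shared0)
    fine_lls = []
    fine_args = []
    for g, (counts, f0) in enumerate(zip((counts_a, counts_b), frees0)):
        axes = [None, None, None]
        axes[j] = shared_axis
        for slot, k in enumerate(others):
            axes[k] = _fine_axis(float(COARSE[f0[slot]]), half=0.03)
        ll = _cube_loglik(counts.n_action, counts.n_inaction, *axes)
        # reduce free axes, keep the shared axis
        red = ll.max(axis=others)
        fine_lls.append(red)
        fine_args.append((axes, ll))
    tot = fine_lls[0] + fine_lls[1]
    s_idx = int(np.argmax(tot))
    params = []
    for axes, ll in fine_args:
        sl = np.take(ll, s_idx, axis=j)
        fidx = np.unravel_index(np.argmax(sl), sl.shape)
        vals = [0.0, 0.0, 0.0]
        vals[j] = float(shared_axis[s_idx])
        for slot, k in enumerate(others):
            vals[k] = float(axes[k][fidx[slot]])
        params.append(tuple(vals))
    return params, float(tot[s_idx])


def saturated_loglik(counts) -> float:
    ll = 0.0
    t = counts.n_action + counts.n_inaction
    for obs in (counts.n_action, counts.n_inaction):
        mask = obs > 0
        ll += float(obs[mask] @ np.log(obs[mask] / t[mask]))
    return ll
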