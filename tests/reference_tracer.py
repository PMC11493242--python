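"""Independent exhaustive photon-split-tree enumeration, used as a test oracle.

A deliberately naive, pure-Python recursive tracer: it walks the *entire*
binary transmitted/reflected tree of a photon, using only the public
primitives (`sample_trilinear`, `gradient_at`, `evaluate_tf`, `schlick`,
`split_photon`) and plain Python control flow.  It shares none of the
compiled tracer's code, so per-cell agreement between the two is a real
cross-check of the recursion, the marching geometry and the bookkeeping.
"""

from __future__ import annotations

import numpy as np

from lumivox.lightfield import PrecomputeConfig, schlick, split_photon
from lumivox.volume_io import (
    TransferFunction,
    Volume,
    evaluate_tf,
    gradient_at,
    sample_trilinear,
)


def _clip_to_box(pos, direction, vol: Volume):
    lo = np.asarray(vol.origin) - 0.5 * np.asarray(vol.spacing)
    hi = np.asarray(vol.origin) + (np.asarray(vol.shape) - 0.5) * np.asarray(vol.spacing)
    t0, t1 = 0.0, np.inf
    for ax in range(3):
        d = direction[ax]
        if abs(d) < 1e-300:
            if pos[ax] < lo[ax] or pos[ax] > hi[ax]:
                return None
        else:
            ta = (lo[ax] - pos[ax]) / d
            tb = (hi[ax] - pos[ax]) / d
            if ta > tb:
                ta, tb = tb, ta
            t0 = max(t0, ta)
            t1 = min(t1, tb)
    if t1 <= t0:
        return None
    return t0, t1


def _cell_of(vol: Volume, p):
    f = (np.asarray(p) - np.asarray(vol.origin)) / np.asarray(vol.spacing)
    idx = np.floor(f + 0.5).astype(int)
    return tuple(np.clip(idx, 0, np.asarray(vol.shape) - 1))


def enumerate_split_tree(
    pos,
    direction,
    energy: float,
    depth: int,
    vol: Volume,
    tf: TransferFunction,
    cfg: PrecomputeConfig,
    deposits: np.ndarray,
):
    """Recursively trace one photon and all descendants.

    Mutates ``deposits`` (same shape as the volume) and returns the energy
    ledger ``(deposited, exited, dropped)``.
    """
    pos = np.asarray(pos, dtype=np.float64)
    direction = np.asarray(direction, dtype=np.float64)
    step_mm = cfg.step * min(vol.spacing)
    clipped = _clip_to_box(pos, direction, vol)
    if clipped is None:
        return 0.0, energy, 0.0
    t0, t1 = clipped

    deposited = exited = dropped = 0.0
    e = energy
    t = t0 + 0.5 * step_mm
    alive = True
    while t < t1:
        p = pos + t * direction
        intensity = sample_trilinear(vol, p, clamp=True)
        alpha = float(evaluate_tf(tf, intensity)[3])
        if alpha > 0.0:
            grad = gradient_at(vol, p)
            gnorm = float(np.linalg.norm(grad))
            if gnorm >= cfg.gradient_threshold:
                cos_hv = abs(float(grad @ direction)) / gnorm
                fr = schlick(cos_hv, cfg.f0)
                lt, lr, lc = split_photon(e, alpha, fr)
                if lr > 0.0:
                    if lr >= cfg.epsilon and depth + 1 <= cfg.max_depth:
                        n = grad / gnorm
                        refl = direction - 2.0 * float(direction @ n) * n
                        refl = refl / np.linalg.norm(refl)
                        d2, x2, r2 = enumerate_split_tree(
                            p, refl, lr, depth + 1, vol, tf, cfg, deposits
                        )
                        deposited += d2
                        exited += x2
                        dropped += r2
                    else:
                        dropped += lr
            else:
                lt = e * (1.0 - alpha)
                lc = e - lt
            deposits[_cell_of(vol, p)] += lc
            deposited += lc
            e = lt
            if e < cfg.epsilon:
                dropped += e
                alive = False
                break
        t += step_mm
    if alive:
        exited += e
    return deposited, exited, dropped
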