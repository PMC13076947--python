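"""Shared test utilities: finite-difference gradient checking."""

import numpy as np


def numeric_grad(loss_fn, param, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of ``loss_fn()`` w.r.t. ``param.data``."""
    grad = np.zeros_like(param.data)
    flat = param.data.ravel()
    gflat = grad.ravel()
    for k in range(flat.size):
        orig = flat[k]
        flat[k] = orig + eps
        up = loss_fn()
        flat[k] = orig - eps
        down = loss_fn()
        flat[k] = orig
        gflat[k] = (up - down) / (2 * eps)
    return grad


def max_rel_err(a: np.ndarray, b: np.ndarray) -> float:
    """Largest elementwise relative error.  The magnitude floor keeps
    central-difference rounding noise (~1e-10 absolute at eps=1e-6) from
    dominating entries whose true gradient is essentially zero."""
    denom = np.maximum(np.maximum(np.abs(a), np.abs(b)), 1e-4)
    return float(np.max(np.abs(a - b) / denom))


def check_gradients(loss_fn, params, rtol: float = 1e-4) -> None:
    """Assert autodiff gradients match central differences for each param."""
    loss = loss_fn()
    for p in params:
        p.grad = None
    loss.backward()
    for p in params:
        analytic = p.grad if p.grad is not None else np.zeros_like(p.data)
        numeric = numeric_grad(lambda: float(loss_fn().data), p)
        err = max_rel_err(analytic, numeric)
        assert err < rtol, f"gradient mismatch {err:.2e} for shape {p.shape}"
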