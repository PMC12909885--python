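"""Low-level array ops for the CPU training engine.

Convolutions are computed by im2col/col2im so that forward, input-gradient
and weight-gradient all reduce to one matrix product each.  Transposed
convolution reuses the same machinery with the roles of forward and
input-gradient swapped.  All tensors are NCHW, float32 by default.
"""

from __future__ import annotations

import numpy as np


def conv_out_size(size: int, k: int, stride: int, dilation: int, pad: int) -> int:
    eff = dilation * (k - 1) + 1
    return (size + 2 * pad - eff) // stride + 1


def im2col(x: np.ndarray, k: int, stride: int = 1, dilation: int = 1, pad: int = 0):
    """(B,C,H,W) -> (B, C*k*k, L) patch matrix, L = h_out*w_out."""
    b, c, h, w = x.shape
    h_out = conv_out_size(h, k, stride, dilation, pad)
    w_out = conv_out_size(w, k, stride, dilation, pad)
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    patches = np.empty((b, c, k * k, h_out * w_out), dtype=x.dtype)
    for idx in range(k * k):
        i0 = dilation * (idx // k)
        j0 = dilation * (idx % k)
        view = x[:, :, i0:i0 + stride * h_out:stride,
                 j0:j0 + stride * w_out:stride]
        patches[:, :, idx, :] = view.reshape(b, c, -1)
    return patches.reshape(b, c * k * k, -1), h_out, w_out


def col2im(cols: np.ndarray, x_shape, k: int, stride: int = 1,
           dilation: int = 1, pad: int = 0) -> np.ndarray:
    """Adjoint of im2col: scatter-add patches back to (B,C,H,W)."""
    b, c, h, w = x_shape
    h_out = conv_out_size(h, k, stride, dilation, pad)
    w_out = conv_out_size(w, k, stride, dilation, pad)
    xp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    patches = cols.reshape(b, c, k * k, h_out, w_out)
    for idx in range(k * k):
        i0 = dilation * (idx // k)
        j0 = dilation * (idx % k)
        xp[:, :, i0:i0 + stride * h_out:stride,
           j0:j0 + stride * w_out:stride] += patches[:, :, idx]
    if pad:
        xp = xp[:, :, pad:-pad, pad:-pad]
    return xp


def conv2d_forward(x, weight, bias, stride=1, dilation=1, pad=0):
    """weight: (Cout, Cin, k, k).  Returns (out, cache)."""
    co, ci, k, _ = weight.shape
    cols, h_out, w_out = im2col(x, k, stride, dilation, pad)
    wf = weight.reshape(co, ci * k * k)
    out = np.matmul(wf, cols)
    if bias is not None:
        out += bias[None, :, None]
    out = out.reshape(x.shape[0], co, h_out, w_out)
    return out, (x.shape, cols, wf)


def conv2d_backward(grad_out, weight, cache, stride=1, dilation=1, pad=0,
                    with_bias=True):
    x_shape, cols, wf = cache
    co, ci, k, _ = weight.shape
    b = grad_out.shape[0]
    g = grad_out.reshape(b, co, -1)
    # sum_b g_b @ cols_b^T as one flat GEMM (avoids a (B,Co,CKK) intermediate)
    g_cat = g.transpose(1, 0, 2).reshape(co, -1)
    cols_cat = cols.transpose(0, 2, 1).reshape(-1, ci * k * k)
    grad_w = (g_cat @ cols_cat).reshape(weight.shape)
    grad_b = g.sum(axis=(0, 2)) if with_bias else None
    grad_cols = np.matmul(wf.T, g)
    grad_x = col2im(grad_cols, x_shape, k, stride, dilation, pad)
    return grad_x, grad_w, grad_b


def conv_transpose2d_forward(x, weight, bias, stride=2, pad=1):
    """weight: (Cin, Cout, k, k).  Output size (H-1)*stride - 2*pad + k."""
    b, ci, h, w = x.shape
    _, co, k, _ = weight.shape
    h_out = (h - 1) * stride - 2 * pad + k
    w_out = (w - 1) * stride - 2 * pad + k
    wf = weight.reshape(ci, co * k * k)
    xf = x.reshape(b, ci, -1)
    cols = np.matmul(wf.T, xf)
    out = col2im(cols, (b, co, h_out, w_out), k, stride, 1, pad)
    if bias is not None:
        out += bias[None, :, None, None]
    return out, (xf, wf, x.shape)


def conv_transpose2d_backward(grad_out, weight, cache, stride=2, pad=1):
    xf, wf, x_shape = cache
    ci, co, k, _ = weight.shape
    gcols, _, _ = im2col(grad_out, k, stride, 1, pad)   # (B, Cout*k*k, L)
    grad_x = np.matmul(wf, gcols).reshape(x_shape)
    x_cat = xf.transpose(1, 0, 2).reshape(ci, -1)
    g_cat = gcols.transpose(0, 2, 1).reshape(-1, co * k * k)
    grad_w = (x_cat @ g_cat).reshape(weight.shape)
    grad_b = grad_out.sum(axis=(0, 2, 3))
    return grad_x, grad_w, grad_b


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits, axis=-1):
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
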