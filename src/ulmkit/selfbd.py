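"""Self-supervised adaptation to unknown PSFs (SelfBD-net).

When a CEUS system's trace morphology differs from anything in the
supervised training set, a second network (the k-net) learns the local PSF
directly from raw frames.  The k-net deforms a fixed Gaussian disk into
the kernel; the pretrained localizer (the x-net) supplies sparse center
estimates.  Both are trained with losses built only from raw frames:

    L_y = a1 ||xk - y||^2 + a2 ||grad(xk) - grad y||^2
          + a3 ||H(xk) - H y||^2        (xk = downsample(x (*) upsample(k)))
    R_x = a4 ||tanh(5 x)||_1 + a5 ||tanh(5 grad x)||_1
    R_k = gamma ||k||^2

with L_k = L_y + R_k driving the k-net and L_x = L_y + R_x the x-net.
The gradient and Hessian channels carry less speckle corruption than raw
intensity, and the Hessian encodes trace shape, which is what lets the
k-net recover elongation and orientation from noisy data.  The tanh
surrogate approximates the L0 counting norms of blind deconvolution while
staying differentiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import GridSpec
from .nn import Adam, Conv2d, InstanceNorm, LeakyReLU, ResBlock, Sequential
from .psf import PSFModel
from .supbd import SupBDNet, _conv_block


@dataclass(frozen=True)
class KNetSpec:
    """k-net architecture: SupBD-net backbone variant, no upscale/squash."""

    n_res_blocks: int = 3
    feature_channels: int = 32
    kernel: int = 7
    leaky_slope: float = 0.2
    disk_sigma_px: float = 5.0  # input Gaussian disk, native pixels


@dataclass(frozen=True)
class SelfLossWeights:
    """Weights of the self-supervised losses (namespaced separately from
    the blind-deconvolution alphas)."""

    alpha1: float = 1.0  # intensity
    alpha2: float = 5.0  # gradient
    alpha3: float = 25.0  # Hessian terms
    alpha4: float = 4e-3  # tanh sparsity on x
    alpha5: float = 4e-3  # tanh sparsity on grad x
    gamma: float = 2.0  # kernel energy

    def __post_init__(self) -> None:
        if min(self.alpha1, self.alpha2, self.alpha3, self.alpha4, self.alpha5, self.gamma) <= 0:
            raise ValueError("all weights must be positive")


class KNet:
    """Deforms a Gaussian disk into the local PSF (native 80 x 80 grid)."""

    def __init__(self, spec: KNetSpec, rng: np.random.Generator):
        self.spec = spec
        c = spec.feature_channels
        k = spec.kernel
        self.stage1 = Sequential(
            _conv_block(1, c, k, spec.leaky_slope, rng),
            _conv_block(c, c, k, spec.leaky_slope, rng),
        )
        self.body = Sequential(
            *[ResBlock(c, k, rng, spec.leaky_slope) for _ in range(spec.n_res_blocks)]
        )
        self.tail = Sequential(Conv2d(c, 1, k, rng))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.ndim == 3:
            x = x[:, None]
        x = x.astype(np.float32, copy=False)
        s1 = self.stage1.forward(x, train=train)
        b = self.body.forward(s1, train=train)
        return self.tail.forward(b + s1, train=train)[:, 0]

    __call__ = forward

    def backward(self, dout: np.ndarray) -> np.ndarray:
        df = self.tail.backward(dout[:, None].astype(np.float32, copy=False))
        db = self.body.backward(df)
        return self.stage1.backward(df + db)

    def param_items(self):
        items = []
        for gname, group in (("stage1", self.stage1), ("body", self.body), ("tail", self.tail)):
            items.extend(group.param_items(gname + "."))
        return items

    def zero_grad(self) -> None:
        for group in (self.stage1, self.body, self.tail):
            group.zero_grad()


def build_knet(spec: KNetSpec | None = None, seed: int = 0) -> KNet:
    return KNet(spec or KNetSpec(), np.random.default_rng(seed))


def embed_kernel(kernel: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Center a (possibly smaller) kernel on a window-sized canvas.

    The self-supervised losses convolve kernels defined on the full
    interrogation window; externally estimated kernels are padded (or
    cropped) so their center pixel lands on ``shape // 2``.
    """
    kernel = np.asarray(kernel, dtype=float)
    out = np.zeros(shape)
    kc = (kernel.shape[0] // 2, kernel.shape[1] // 2)
    oc = (shape[0] // 2, shape[1] // 2)
    i0, j0 = oc[0] - kc[0], oc[1] - kc[1]
    si0, sj0 = max(i0, 0), max(j0, 0)
    si1 = min(i0 + kernel.shape[0], shape[0])
    sj1 = min(j0 + kernel.shape[1], shape[1])
    out[si0:si1, sj0:sj1] = kernel[si0 - i0 : si1 - i0, sj0 - j0 : sj1 - j0]
    return out


def gaussian_disk(shape: tuple[int, int], sigma_px: float) -> np.ndarray:
    """Unit-peak Gaussian disk centered on the window (k-net input)."""
    dd = np.arange(shape[0]) - shape[0] // 2
    ll = np.arange(shape[1]) - shape[1] // 2
    g = np.exp(-0.5 * ((dd[:, None] / sigma_px) ** 2 + (ll[None, :] / sigma_px) ** 2))
    return g.astype(np.float32)


# ---------------------------------------------------------------------------
# fixed linear resampling operators (bicubic, with exact adjoints)


def _cubic(t: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Keys cubic interpolation kernel."""
    t = np.abs(t)
    out = np.zeros_like(t)
    m1 = t <= 1
    out[m1] = (a + 2) * t[m1] ** 3 - (a + 3) * t[m1] ** 2 + 1
    m2 = (t > 1) & (t < 2)
    out[m2] = a * t[m2] ** 3 - 5 * a * t[m2] ** 2 + 8 * a * t[m2] - 4 * a
    return out


def _resample_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1D bicubic resampling matrix with pixel-center alignment.

    Downsampling stretches the kernel by the scale factor (antialiasing),
    matching the convention of standard bicubic image resizing.
    """
    scale = n_out / n_in
    stretch = max(1.0, 1.0 / scale)
    out_pos = (np.arange(n_out) + 0.5) / scale - 0.5
    offsets = np.arange(-int(np.ceil(2 * stretch)), int(np.ceil(2 * stretch)) + 1)
    base = np.floor(out_pos).astype(int)
    M = np.zeros((n_out, n_in))
    for off in offsets:
        idx = base + off
        w = _cubic((idx - out_pos) / stretch) / stretch
        idx_c = np.clip(idx, 0, n_in - 1)  # replicate edges
        np.add.at(M, (np.arange(n_out), idx_c), w)
    # normalize rows so constants are preserved
    M /= M.sum(axis=1, keepdims=True)
    return M


class Resampler:
    """Separable bicubic up/down sampling as explicit linear maps."""

    def __init__(self, n_native: int, factor: int):
        self.U = _resample_matrix(n_native, n_native * factor)
        self.D = _resample_matrix(n_native * factor, n_native)

    def up(self, img: np.ndarray) -> np.ndarray:
        return self.U @ img @ self.U.T

    def up_adjoint(self, g: np.ndarray) -> np.ndarray:
        return self.U.T @ g @ self.U

    def down(self, img: np.ndarray) -> np.ndarray:
        return self.D @ img @ self.D.T

    def down_adjoint(self, g: np.ndarray) -> np.ndarray:
        return self.D.T @ g @ self.D


class _CenteredConv:
    """'Same'-size 2D convolution of equal-sized arrays, with adjoints.

    ``conv(a, b)[i] = sum_s a[s] b[i - s + c]`` with ``c = shape // 2``;
    implemented by FFT on the doubled grid.
    """

    def __init__(self, shape: tuple[int, int]):
        self.shape = shape
        self.pad = (2 * shape[0], 2 * shape[1])
        self.c = (shape[0] // 2, shape[1] // 2)

    def _fft(self, a: np.ndarray) -> np.ndarray:
        return np.fft.rfft2(a, s=self.pad)

    def conv(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        full = np.fft.irfft2(self._fft(a) * self._fft(b), s=self.pad)
        c0, c1 = self.c
        return full[c0 : c0 + self.shape[0], c1 : c1 + self.shape[1]]

    def _embed(self, g: np.ndarray) -> np.ndarray:
        z = np.zeros(self.pad)
        c0, c1 = self.c
        z[c0 : c0 + self.shape[0], c1 : c1 + self.shape[1]] = g
        return z

    def adjoint_a(self, g: np.ndarray, b: np.ndarray) -> np.ndarray:
        out = np.fft.irfft2(np.conj(self._fft(b)) * np.fft.rfft2(self._embed(g)), s=self.pad)
        return out[: self.shape[0], : self.shape[1]]

    def adjoint_b(self, g: np.ndarray, a: np.ndarray) -> np.ndarray:
        out = np.fft.irfft2(np.conj(self._fft(a)) * np.fft.rfft2(self._embed(g)), s=self.pad)
        return out[: self.shape[0], : self.shape[1]]


# periodic finite-difference stencils (adjoints are exact under wrap)


def _d_lat(r):
    return 0.5 * (np.roll(r, -1, axis=-1) - np.roll(r, 1, axis=-1))


def _d_dep(r):
    return 0.5 * (np.roll(r, -1, axis=-2) - np.roll(r, 1, axis=-2))


def _d2_lat(r):
    return np.roll(r, -1, axis=-1) - 2 * r + np.roll(r, 1, axis=-1)


def _d2_dep(r):
    return np.roll(r, -1, axis=-2) - 2 * r + np.roll(r, 1, axis=-2)


def _loss_channels(r: np.ndarray, w: SelfLossWeights) -> tuple[float, np.ndarray]:
    """Weighted intensity/gradient/Hessian L2 of a residual, plus gradient.

    Gradients use central differences and the four Hessian entries use
    second differences; the cross term appears twice (H is symmetric), so
    all four matrix entries contribute as stated.
    """
    gl, gd = _d_lat(r), _d_dep(r)
    hll, hdd = _d2_lat(r), _d2_dep(r)
    hld = _d_lat(_d_dep(r))
    loss = (
        w.alpha1 * np.sum(r**2)
        + w.alpha2 * (np.sum(gl**2) + np.sum(gd**2))
        + w.alpha3 * (np.sum(hll**2) + np.sum(hdd**2) + 2.0 * np.sum(hld**2))
    )
    # adjoints: central difference is skew (D^T = -D), second difference is
    # symmetric; both are their own wrap-around stencils up to sign
    grad = 2.0 * (
        w.alpha1 * r
        - w.alpha2 * (_d_lat(gl) + _d_dep(gd))
        + w.alpha3 * (_d2_lat(hll) + _d2_dep(hdd) + 2.0 * _d_dep(_d_lat(hld)))
    )
    return float(loss), grad


@dataclass
class _SelfOps:
    """Cached operators for a given window geometry."""

    resampler: Resampler
    conv: _CenteredConv


_ops_cache: dict[tuple[int, int], _SelfOps] = {}


def _get_ops(n_native: int, factor: int) -> _SelfOps:
    key = (n_native, factor)
    if key not in _ops_cache:
        _ops_cache[key] = _SelfOps(
            Resampler(n_native, factor),
            _CenteredConv((n_native * factor, n_native * factor)),
        )
    return _ops_cache[key]


def self_loss_y(
    x_tilde: np.ndarray,
    k_tilde: np.ndarray,
    y: np.ndarray,
    weights: SelfLossWeights | None = None,
    superres_factor: int = 3,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Raw-frame reconstruction loss; returns (loss, dL/dx, dL/dk).

    ``x_tilde``: (B, fH, fW) super-resolved center maps; ``k_tilde``:
    (H, W) native kernel; ``y``: (B, H, W) raw frames.  The kernel is
    bicubically upsampled to the super-resolved grid, convolved with each
    center map, downsampled back to native, and compared with the frame on
    the intensity, gradient, and Hessian channels.
    """
    weights = weights or SelfLossWeights()
    x_tilde = np.atleast_3d(np.asarray(x_tilde, dtype=float))
    if x_tilde.ndim == 2:
        x_tilde = x_tilde[None]
    y = np.asarray(y, dtype=float)
    if y.ndim == 2:
        y = y[None]
    n_native = y.shape[-1]
    if y.shape[-2] != n_native or k_tilde.shape != (n_native, n_native):
        raise ValueError("kernel and frames must be square and same size")
    if x_tilde.shape[-1] != n_native * superres_factor or x_tilde.shape[0] != y.shape[0]:
        raise ValueError("x_tilde shape does not match frames at the superres factor")

    ops = _get_ops(n_native, superres_factor)
    k_up = ops.resampler.up(np.asarray(k_tilde, dtype=float))
    total = 0.0
    grad_x = np.zeros_like(x_tilde)
    grad_kup = np.zeros_like(k_up)
    for b in range(len(y)):
        z = ops.conv.conv(x_tilde[b], k_up)
        yhat = ops.resampler.down(z)
        loss_b, grad_r = _loss_channels(yhat - y[b], weights)
        total += loss_b
        grad_z = ops.resampler.down_adjoint(grad_r)
        grad_x[b] = ops.conv.adjoint_a(grad_z, k_up)
        grad_kup += ops.conv.adjoint_b(grad_z, x_tilde[b])
    grad_k = ops.resampler.up_adjoint(grad_kup)
    return float(total), grad_x, grad_k


def reg_x(
    x_tilde: np.ndarray, weights: SelfLossWeights | None = None
) -> tuple[float, np.ndarray]:
    """tanh surrogate of the L0 priors on the center map; (loss, grad)."""
    weights = weights or SelfLossWeights()
    x = np.asarray(x_tilde, dtype=float)
    t = np.tanh(5.0 * x)
    loss = weights.alpha4 * np.sum(np.abs(t))
    grad = weights.alpha4 * np.sign(t) * 5.0 * (1.0 - t**2)
    # forward differences of x
    for axis in (-2, -1):
        d = np.roll(x, -1, axis=axis) - x
        td = np.tanh(5.0 * d)
        loss += weights.alpha5 * np.sum(np.abs(td))
        g = weights.alpha5 * np.sign(td) * 5.0 * (1.0 - td**2)
        grad += np.roll(g, 1, axis=axis) - g  # adjoint of forward difference
    return float(loss), grad


def reg_k(
    k_tilde: np.ndarray, weights: SelfLossWeights | None = None
) -> tuple[float, np.ndarray]:
    """Kernel energy penalty gamma ||k||_2^2; (loss, grad)."""
    weights = weights or SelfLossWeights()
    k = np.asarray(k_tilde, dtype=float)
    return float(weights.gamma * np.sum(k**2)), 2.0 * weights.gamma * k


def sparsify_detections(x_tilde: np.ndarray, min_peak: float = 0.5) -> np.ndarray:
    """Keep only the brightest super-threshold pixel of each cluster.

    Clusters are 8-connected components of the ``> min_peak`` support; ties
    resolve to the first pixel in row-major scan order, so the result is
    deterministic.
    """
    x = np.asarray(x_tilde, dtype=float)
    out = np.zeros_like(x)
    mask = x > min_peak
    if not mask.any():
        return out
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    flat = x.ravel()
    lab_flat = labels.ravel()
    for comp in range(1, n + 1):
        idx = np.flatnonzero(lab_flat == comp)
        best = idx[np.argmax(flat[idx])]  # argmax returns the first maximum
        out.ravel()[best] = flat[best]
    return out


# ---------------------------------------------------------------------------
# step 1: adapt the k-net


@dataclass
class AdaptConfig:
    n_frames: int = 8
    lr: float = 1e-3
    lr_decay: float = 0.1
    lr_patience: int = 5  # iterations without L_k decrease
    max_lr_reductions: int = 2
    rms_tol: float = 1e-6
    max_iters: int = 300
    #: iteration cap for pre-fitting the k-net output to the disk itself,
    #: so adaptation starts from the disk and deforms it
    disk_prefit_iters: int = 300
    seed: int = 0


@dataclass
class AdaptLog:
    loss: list[float] = field(default_factory=list)
    kernel_rms_change: list[float] = field(default_factory=list)
    converged_iter: int | None = None


def adapt_knet(
    window_frames: np.ndarray,
    xnet: SupBDNet,
    knet: KNet,
    weights: SelfLossWeights | None = None,
    config: AdaptConfig | None = None,
    grid: GridSpec | None = None,
) -> tuple[PSFModel, AdaptLog]:
    """Estimate the window's PSF by training the k-net only.

    A fixed random subset of frames is pushed through the frozen x-net and
    sparsified (brightest peak per cluster above 0.5); the k-net then
    learns to deform the Gaussian disk so the reconstruction matches those
    frames.  Training stops when successive kernel estimates differ by an
    RMS below ``rms_tol``.
    """
    weights = weights or SelfLossWeights()
    config = config or AdaptConfig()
    grid = grid or GridSpec()
    frames = np.asarray(window_frames, dtype=np.float32)
    if frames.ndim == 2:
        frames = frames[None]
    if len(frames) < config.n_frames:
        raise ValueError(f"need at least {config.n_frames} frames")
    rng = np.random.default_rng(config.seed)
    sel = rng.choice(len(frames), size=config.n_frames, replace=False)
    batch = frames[sel]

    x_maps = xnet.forward(batch, train=False)
    x_sparse = np.stack([sparsify_detections(m) for m in x_maps])
    if not (x_sparse > 0).any():
        raise ValueError("no detections in any selected frame")

    disk = gaussian_disk(frames.shape[-2:], knet.spec.disk_sigma_px)
    # start from the disk: fit the randomly initialized net to reproduce
    # its input before deforming it toward the data
    pre_opt = Adam(knet.param_items(), lr=1e-2)
    for _ in range(config.disk_prefit_iters):
        out = knet.forward(disk[None], train=True)
        diff = out - disk[None]
        rel = np.sqrt(np.mean(diff**2)) / np.sqrt(np.mean(disk**2))
        if rel < 0.05:
            break
        knet.zero_grad()
        knet.backward(2.0 * diff)  # sum-scale gradient, matching the main loss
        pre_opt.step()

    opt = Adam(knet.param_items(), lr=config.lr)
    log = AdaptLog()
    k_prev = None
    best_loss = np.inf
    best_kernel = None
    stall = 0
    reductions = 0
    factor = grid.superres_factor
    for it in range(config.max_iters):
        k_raw = knet.forward(disk[None], train=True)[0].astype(float)
        scale = float(np.abs(k_raw).max())
        if scale == 0:
            scale = 1.0
        k_used = k_raw / scale  # unit peak in the forward model (scale frozen)
        loss_y, _, grad_k_used = self_loss_y(x_sparse, k_used, batch, weights, factor)
        loss_rk, grad_rk = reg_k(k_raw, weights)
        loss_k = loss_y + loss_rk
        grad_k = grad_k_used / scale + grad_rk
        knet.zero_grad()
        knet.backward(grad_k[None].astype(np.float32))
        opt.step()
        log.loss.append(loss_k)
        if loss_k < best_loss - 1e-12:
            best_loss = loss_k
            best_kernel = k_used.copy()
            stall = 0
        else:
            stall += 1
            if stall >= config.lr_patience and reductions < config.max_lr_reductions:
                opt.lr *= config.lr_decay
                reductions += 1
                stall = 0
        if k_prev is not None:
            rms = float(np.sqrt(np.mean((k_used - k_prev) ** 2)))
            log.kernel_rms_change.append(rms)
            if rms < config.rms_tol:
                log.converged_iter = it
                break
        k_prev = k_used
    kernel = best_kernel if best_kernel is not None else k_used
    kernel = np.clip(kernel, 0.0, None)
    model = PSFModel.from_kernel(
        kernel,
        native_pixel_um=grid.native_pixel_um,
        synthesis_factor=grid.synthesis_factor,
        family="knet",
    )
    return model, log


# ---------------------------------------------------------------------------
# step 2: refine the x-net


@dataclass
class RefineConfig:
    n_val: int = 8
    minibatch: int = 8
    lr: float = 1e-4
    lr_decay: float = 0.1
    validate_every: int = 5  # iterations
    lr_patience: int = 5  # validations without improvement
    max_reductions: int = 3
    max_iters: int = 300
    seed: int = 0


@dataclass
class RefineLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    reductions: int = 0


def refine_xnet(
    window_frames: np.ndarray,
    psf_kernel: np.ndarray,
    xnet: SupBDNet,
    weights: SelfLossWeights | None = None,
    config: RefineConfig | None = None,
    grid: GridSpec | None = None,
) -> tuple[SupBDNet, RefineLog]:
    """Refine the layers after the global residual addition of the x-net.

    With the adapted kernel frozen, minibatches of raw frames minimize
    ``L_x = L_y + R_x``; a held-out set of frames is scored every few
    iterations, the learning rate drops tenfold on validation stalls
    (three times in total), and the best-validated parameters are kept.
    """
    weights = weights or SelfLossWeights()
    config = config or RefineConfig()
    grid = grid or GridSpec()
    frames = np.asarray(window_frames, dtype=np.float32)
    if frames.ndim == 2:
        frames = frames[None]
    if len(frames) < 2 * config.n_val:
        raise ValueError("too few frames to split into training and validation")
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(frames))
    val, train = frames[perm[: config.n_val]], frames[perm[config.n_val :]]
    kernel = embed_kernel(np.asarray(psf_kernel, dtype=float), frames.shape[-2:])
    kernel = kernel / kernel.max()
    factor = grid.superres_factor

    def x_loss(batch: np.ndarray, train_mode: bool):
        x = xnet.forward(batch, train=train_mode).astype(float)
        ly, gx, _ = self_loss_y(x, kernel, batch, weights, factor)
        lr_, gr = reg_x(x, weights)
        return ly + lr_, gx + gr

    opt = Adam(xnet.tail_param_items(), lr=config.lr)
    log = RefineLog()
    best_val = np.inf
    best_state = xnet.state_dict()
    stall = 0
    for it in range(config.max_iters):
        idx = rng.choice(len(train), size=min(config.minibatch, len(train)), replace=False)
        loss, grad = x_loss(train[idx], True)
        xnet.zero_grad()
        xnet.backward(grad.astype(np.float32))
        opt.step()
        log.train_loss.append(loss)
        if (it + 1) % config.validate_every == 0:
            vloss, _ = x_loss(val, False)
            log.val_loss.append(vloss)
            if vloss < best_val - 1e-12:
                best_val = vloss
                best_state = xnet.state_dict()
                stall = 0
            else:
                stall += 1
                if stall >= config.lr_patience:
                    opt.lr *= config.lr_decay
                    log.reductions += 1
                    stall = 0
                    if log.reductions >= config.max_reductions:
                        break
    xnet.load_state_dict(best_state)
    return xnet, log
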