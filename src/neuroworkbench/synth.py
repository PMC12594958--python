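"""Synthetic-data generators with exact ground truth.

Every pipeline input the package consumes can be generated here with known
planted structure: puncta pairs on curvilinear filaments, calcium traces
with bleaching baselines and exponential transients, voltage-clamp sweeps
with capacitive transients and template ionic currents, cohorts of deformed
brain outlines carrying latent stiffness/fluorescence fields, per-guide
Bernoulli-edited amplicon clones, and neurite trees for Sholl profiling.
All generators are deterministic given (parameters, seed) and return a
GroundTruth record sufficient to score any downstream detector exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .brainmap import BrainSample
from .calcium import TraceMatrix
from .ephys import SweepSet
from .puncta import MultiChannelImage

__all__ = [
    "GroundTruth",
    "make_synapse_image",
    "make_calcium_traces",
    "make_sweepset",
    "make_brain_cohort",
    "make_amplicons",
    "make_sholl_cell",
]


@dataclass
class GroundTruth:
    """Planted-object table plus generator extras (latent fields etc.)."""

    kind: Literal["puncta", "transients", "sweeps", "brains", "amplicons", "sholl"]
    records: pd.DataFrame
    seed: int
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# synapse images


def _draw_filaments(
    shape: tuple[int, int], n_filaments: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    """Smoothed-random-walk filaments rasterised ~2 px wide.

    Returns (mask, path_points (k, 2) row/col, total arc length in px).
    """
    h, w = shape
    paths = []
    total_len = 0.0
    for _ in range(n_filaments):
        edge = rng.integers(4)
        if edge == 0:
            pos = np.array([0.0, rng.uniform(0, w)])
        elif edge == 1:
            pos = np.array([h - 1.0, rng.uniform(0, w)])
        elif edge == 2:
            pos = np.array([rng.uniform(0, h), 0.0])
        else:
            pos = np.array([rng.uniform(0, h), w - 1.0])
        centre = np.array([h / 2, w / 2])
        angle = float(np.arctan2(*(centre - pos))) + rng.normal(0, 0.3)
        pts = [pos.copy()]
        for _ in range(4 * max(h, w)):
            angle += rng.normal(0.0, 0.08)
            pos = pos + np.array([np.sin(angle), np.cos(angle)])
            if not (0 <= pos[0] < h and 0 <= pos[1] < w):
                break
            pts.append(pos.copy())
        if len(pts) > 5:
            paths.append(np.asarray(pts))
            total_len += len(pts) - 1  # unit steps
    mask = np.zeros(shape, dtype=bool)
    if paths:
        allpts = np.vstack(paths)
        idx = np.clip(np.round(allpts).astype(int), 0, [h - 1, w - 1])
        hit = np.zeros(shape, dtype=bool)
        hit[idx[:, 0], idx[:, 1]] = True
        mask = ndimage.distance_transform_edt(~hit) < 1.0
    else:
        allpts = np.empty((0, 2))
    return mask, allpts, total_len


def _add_spot(img: np.ndarray, r: float, c: float, amp: float, sigma: float) -> None:
    rad = int(np.ceil(4 * sigma))
    r0, r1 = max(0, int(r) - rad), min(img.shape[0], int(r) + rad + 1)
    c0, c1 = max(0, int(c) - rad), min(img.shape[1], int(c) + rad + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    img[r0:r1, c0:c1] += amp * np.exp(
        -((rows - r) ** 2 + (cols - c) ** 2) / (2 * sigma**2)
    )


def make_synapse_image(
    n_filaments: int = 4,
    synapse_density: float = 50.0,
    distractor_rate: float = 0.01,
    jitter_px: float = 1.0,
    snr: float = 8.0,
    nf_snr: float = 15.0,
    pixel_nm: float = 180.0,
    shape: tuple[int, int] = (256, 256),
    spot_sigma: float = 1.5,
    seed: int = 0,
) -> tuple[MultiChannelImage, GroundTruth]:
    """Four-channel synthetic FOV with planted synapses and distractors.

    True synapses are pre/post Gaussian-spot pairs whose centres lie within
    ``jitter_px`` of each other and of a filament; distractors are isolated
    spots placed off-filament (violating the neurofilament-proximity
    condition).  ``synapse_density`` is per mm of filament;
    ``distractor_rate`` per um^2 of FOV; SNR is spot peak amplitude over the
    Gaussian read-noise sd.
    """
    if synapse_density < 0:
        raise ValueError("synapse_density must be >= 0")
    if jitter_px < 0 or snr <= 0:
        raise ValueError("jitter_px must be >= 0 and snr > 0")
    if min(shape) < 256:
        raise ValueError("image must be at least 256x256")
    rng = np.random.default_rng(seed)
    h, w = shape
    nf_mask, path_pts, length_px = _draw_filaments(shape, n_filaments, rng)
    length_mm = length_px * pixel_nm * 1e-6

    noise_sd = 1.0
    amp = snr * noise_sd
    channels = {ch: np.zeros(shape) for ch in ("NF", "NRL", "VGLUT2", "VGAT")}
    # neurofilament bundles are dense structures, much brighter than single
    # puncta; their contrast is independent of the punctum SNR
    channels["NF"][nf_mask] = nf_snr * noise_sd
    channels["NF"] = ndimage.gaussian_filter(channels["NF"], 0.8)

    records = []
    n_syn = int(round(synapse_density * length_mm)) if len(path_pts) else 0
    margin = 8
    interior = [
        p
        for p in path_pts
        if margin <= p[0] < h - margin and margin <= p[1] < w - margin
    ]
    for k in range(n_syn):
        if not interior:
            break
        anchor = interior[rng.integers(len(interior))]
        offsets = []
        for _ in range(2):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, jitter_px / 2.0) if jitter_px > 0 else 0.0
            offsets.append(np.array([np.cos(ang), np.sin(ang)]) * rad)
        pre_ch = "VGLUT2" if rng.random() < 0.5 else "VGAT"
        pre = anchor + offsets[0]
        post = anchor + offsets[1]
        _add_spot(channels[pre_ch], pre[0], pre[1], amp, spot_sigma)
        _add_spot(channels["NRL"], post[0], post[1], amp, spot_sigma)
        records.append((pre_ch, pre[0], pre[1], k, True, "pre"))
        records.append(("NRL", post[0], post[1], k, True, "post"))

    # distractors: off-filament isolated spots
    area_um2 = h * w * (pixel_nm * 1e-3) ** 2
    n_dis = rng.poisson(distractor_rate * area_um2) if distractor_rate > 0 else 0
    far = (
        ndimage.distance_transform_edt(~nf_mask) > 6 + jitter_px
        if nf_mask.any()
        else np.ones(shape, dtype=bool)
    )
    far[:margin] = far[-margin:] = False
    far[:, :margin] = far[:, -margin:] = False
    far_idx = np.argwhere(far)
    for k in range(n_dis):
        if not len(far_idx):
            break
        r, c = far_idx[rng.integers(len(far_idx))] + rng.uniform(-0.5, 0.5, 2)
        ch = ("VGLUT2", "VGAT", "NRL")[rng.integers(3)]
        _add_spot(channels[ch], r, c, amp, spot_sigma)
        records.append((ch, r, c, -1, False, "distractor"))

    for ch in channels:
        channels[ch] = channels[ch] + rng.normal(0, noise_sd, shape)

    truth = pd.DataFrame(
        records, columns=["channel", "row", "col", "pair_id", "is_synapse", "role"]
    )
    gt = GroundTruth(
        kind="puncta",
        records=truth,
        seed=seed,
        extras={
            "nf_mask": nf_mask,
            "filament_length_px": length_px,
            "length_mm": length_mm,
            "spot_sigma": spot_sigma,
            "amp": amp,
            "noise_sd": noise_sd,
        },
    )
    return MultiChannelImage(channels=channels, pixel_nm=pixel_nm), gt


# ---------------------------------------------------------------------------
# calcium traces


def make_calcium_traces(
    n_cells: int = 50,
    frame_ms: float = 80.0,
    n_frames: int = 500,
    bleach_tau_s: float = 60.0,
    transient_rate_hz: float = 0.05,
    amp_dff: float = 0.1,
    decay_s: float = 1.0,
    noise_sd: float = 0.008,
    seed: int = 0,
) -> tuple[TraceMatrix, GroundTruth]:
    """Calcium traces: bleaching baseline times (1 + transients) plus noise.

    trace = baseline * (1 + sum of transients) + baseline * N(0, noise_sd),
    so ``noise_sd`` is expressed in dF/F units.  Transients rise in one frame
    and decay exponentially with ``decay_s``; event frames follow a Poisson
    process of ``transient_rate_hz``.  A cell is active if it has >= 1 event.
    """
    if amp_dff < 0:
        raise ValueError("amp_dff must be >= 0")
    rng = np.random.default_rng(seed)
    dt = frame_ms * 1e-3
    t = np.arange(n_frames) * dt
    duration = n_frames * dt
    traces = np.zeros((n_cells, n_frames))
    rows = []
    baselines = np.zeros_like(traces)
    for c in range(n_cells):
        f0 = rng.uniform(80.0, 120.0)
        baseline = f0 * np.exp(-t / bleach_tau_s)
        s = np.zeros(n_frames)
        n_ev = rng.poisson(transient_rate_hz * duration) if transient_rate_hz > 0 else 0
        frames = np.sort(rng.integers(5, n_frames - 5, size=n_ev))
        for fr in frames:
            s[fr:] += amp_dff * np.exp(-(t[fr:] - t[fr]) / decay_s)
            rows.append((c, int(fr), amp_dff))
        noise = rng.normal(0, noise_sd, n_frames) if noise_sd > 0 else 0.0
        traces[c] = baseline * (1.0 + s) + baseline * noise
        baselines[c] = baseline
    records = pd.DataFrame(rows, columns=["cell", "frame", "amp_dff"])
    active = np.array([c in set(records["cell"]) for c in range(n_cells)])
    gt = GroundTruth(
        kind="transients",
        records=records,
        seed=seed,
        extras={"active": active, "baselines": baselines},
    )
    return TraceMatrix(traces, frame_interval_s=dt), gt


# ---------------------------------------------------------------------------
# patch-clamp sweeps


def _boltzmann(v: np.ndarray, v_half: float, slope: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(v - v_half) / slope))


def make_sweepset(
    rs_mohm: float = 10.0,
    rm_mohm: float = 500.0,
    cm_pf: float = 30.0,
    gna_peak_ns: float = 40.0,
    gk_sustained_ns: float = 20.0,
    noise_sd_pa: float = 0.0,
    seed: int = 0,
) -> tuple[SweepSet, SweepSet, GroundTruth]:
    """Membrane-test sweep plus 20-step IV protocol with template currents.

    The membrane test is a single -5 mV, 50 ms pulse whose capacitive
    transient decays with tau = Cm * Rs*Rm/(Rs+Rm).  IV steps (200 ms, 10 mV
    increments from -120 to +70 mV, holding -60 mV) carry a fast
    Boltzmann-activated, driving-force-scaled transient inward current and a
    sustained outward current plus ohmic leak.  Returns
    (memtest, iv_steps, truth); truth holds the planted passive properties
    and the per-step noiseless peak inward / sustained outward currents.
    """
    if min(rs_mohm, rm_mohm, cm_pf) <= 0:
        raise ValueError("Rs, Rm, Cm must be positive")
    rng = np.random.default_rng(seed)

    # membrane test, 100 kHz
    rate_mt = 100_000.0
    t_mt = np.arange(int(0.05 * rate_mt)) / rate_mt
    r_par = rs_mohm * rm_mohm / (rs_mohm + rm_mohm)  # MOhm
    tau_s = cm_pf * 1e-12 * r_par * 1e6
    dv = -5.0  # mV
    i0 = dv / rs_mohm * 1e3  # pA  (mV/MOhm = nA)
    iss = dv / (rs_mohm + rm_mohm) * 1e3
    i_mt = iss + (i0 - iss) * np.exp(-t_mt / tau_s)
    if noise_sd_pa > 0:
        i_mt = i_mt + rng.normal(0, noise_sd_pa, i_mt.shape)
    memtest = SweepSet(
        time_s=t_mt,
        sweeps=i_mt[None, :],
        mode="vc",
        holding=-60.0,
        levels=np.array([dv]),
        step_start_s=0.0,
        step_dur_s=0.05,
        sample_rate_hz=rate_mt,
    )

    # IV protocol, 20 kHz
    rate = 20_000.0
    pre, dur, post = 0.05, 0.2, 0.05
    n = int((pre + dur + post) * rate)
    t = np.arange(n) / rate
    on = t >= pre
    ts = np.where(on, t - pre, 0.0)
    in_step = (t >= pre) & (t < pre + dur)
    levels = np.arange(-120.0, 70.0 + 1e-9, 10.0)
    e_na, e_k, v_hold = 60.0, -90.0, -60.0
    sweeps = np.zeros((len(levels), n))
    rows = []
    na_shape = (1.0 - np.exp(-ts / 5e-4)) * np.exp(-ts / 2e-3)
    k_shape = 1.0 - np.exp(-ts / 1e-2)
    for idx, v in enumerate(levels):
        i_na = gna_peak_ns * _boltzmann(v, -30.0, 7.0) * (v - e_na) * na_shape
        i_k = gk_sustained_ns * _boltzmann(v, -25.0, 12.0) * (v - e_k) * k_shape
        clean = np.where(in_step, i_na + i_k, 0.0)
        first10 = in_step & (t < pre + 0.01)
        last50 = in_step & (t >= pre + dur - 0.05)
        rows.append(
            (v, float(clean[first10].min()), float(clean[last50].mean()))
        )
        sweeps[idx] = clean + (
            rng.normal(0, noise_sd_pa, n) if noise_sd_pa > 0 else 0.0
        )
    iv = SweepSet(
        time_s=t,
        sweeps=sweeps,
        mode="vc",
        holding=v_hold,
        levels=levels,
        step_start_s=pre,
        step_dur_s=dur,
        sample_rate_hz=rate,
    )
    truth = pd.DataFrame(rows, columns=["voltage_mv", "i_na_true_pa", "i_kdr_true_pa"])
    gt = GroundTruth(
        kind="sweeps",
        records=truth,
        seed=seed,
        extras={
            "rs_mohm": rs_mohm,
            "rm_mohm": rm_mohm,
            "cm_pf": cm_pf,
            "tau_s": tau_s,
        },
    )
    return memtest, iv, gt


# ---------------------------------------------------------------------------
# brain cohorts


def _latent_field(
    rng: np.random.Generator,
    xs: np.ndarray,
    ys: np.ndarray,
    corr_fine: float,
    corr_regional: float,
    fine_share: float,
) -> RegularGridInterpolator:
    """Unit-variance Gaussian random field: local texture + regional trend."""
    dx = xs[1] - xs[0]

    def grf(corr: float) -> np.ndarray:
        white = rng.normal(0, 1, (len(ys), len(xs)))
        sm = ndimage.gaussian_filter(white, corr / dx, mode="reflect")
        return (sm - sm.mean()) / sm.std()

    z = np.sqrt(fine_share) * grf(corr_fine) + np.sqrt(1 - fine_share) * grf(
        corr_regional
    )
    return RegularGridInterpolator(
        (ys, xs), z, bounds_error=False, fill_value=0.0
    )


def make_brain_cohort(
    n_embryos: int = 8,
    effect: Literal["anticorrelated", "independent"] = "anticorrelated",
    deform_sd: float = 0.04,
    n_afm_points: int = 100,
    seed: int = 0,
    latent_r: float = -0.85,
    fine_share: float = 1.0,
    corr_regional: float = 0.5,
) -> tuple[list[BrainSample], GroundTruth]:
    """Cohort of deformed brain outlines with latent stiffness/FM fields.

    A shared elliptical template (half-axes 1.5 x 1.0) carries two latent
    fields defined in template space: a stiffness field (local AFM-site
    heterogeneity dominating a smooth regional trend) and a fluorescence
    field that is either a noisy monotone-decreasing function of stiffness
    (``anticorrelated``, latent correlation ``latent_r``) or an independent
    field of the same spectrum.  Each embryo sees the template through its
    own radial Fourier perturbation (amplitude ``deform_sd``) followed by a
    random affine distortion, and contributes an outline, an AFM grid of
    noisy moduli and an FM1-43 image.
    """
    if n_embryos < 2:
        raise ValueError("need at least 2 embryos")
    rng = np.random.default_rng(seed)
    a_ax, b_ax = 1.5, 1.0
    # grid pitch chosen so that ~n_afm_points nodes fall inside the margin
    area = np.pi * (0.92 * a_ax) * (0.92 * b_ax)
    spacing = float(np.sqrt(area / n_afm_points))

    xs = np.linspace(-1.7, 1.7, 180)
    ys = np.linspace(-1.2, 1.2, 128)
    # by default, AFM-site-scale heterogeneity dominates (neighbouring
    # measurement sites of real maps differ substantially); the field is
    # still smooth at the pixel scale of the fluorescence images.  Lower
    # fine_share for regionally smooth fields.
    stiff_f = _latent_field(rng, xs, ys, corr_fine=0.25 * spacing,
                            corr_regional=corr_regional, fine_share=fine_share)
    indep_f = _latent_field(rng, xs, ys, corr_fine=0.25 * spacing,
                            corr_regional=corr_regional, fine_share=fine_share)
    if effect == "anticorrelated":
        def fm_latent(pts):
            s = stiff_f(pts)
            return latent_r * s + np.sqrt(1 - latent_r**2) * indep_f(pts)
    elif effect == "independent":
        def fm_latent(pts):
            return indep_f(pts)
    else:
        raise ValueError(f"unknown effect {effect!r}")

    def stiff_pa(pts):
        return 200.0 + 70.0 * stiff_f(pts)

    def fm_intensity(pts):
        return 100.0 + 40.0 * fm_latent(pts)

    # AFM template grid inside the ellipse (with margin)
    gx = np.arange(-a_ax, a_ax + spacing / 2, spacing)
    gy = np.arange(-b_ax, b_ax + spacing / 2, spacing)
    mx, my = np.meshgrid(gx, gy)
    inside = (mx / (0.92 * a_ax)) ** 2 + (my / (0.92 * b_ax)) ** 2 <= 1.0
    afm_template = np.column_stack([mx[inside], my[inside]])

    theta_t = np.linspace(0, 2 * np.pi, 300, endpoint=False)
    template_contour = np.column_stack(
        [a_ax * np.cos(theta_t), b_ax * np.sin(theta_t)]
    )

    scale_px = 260.0  # px per template unit (~780 px across the brain)
    samples, rec_rows, transforms = [], [], []
    for e in range(n_embryos):
        ks = np.arange(2, 6)
        amps = rng.normal(0, deform_sd / np.sqrt(ks))
        phases = rng.uniform(0, 2 * np.pi, len(ks))

        def radial(p):
            th = np.arctan2(p[..., 1], p[..., 0])
            f = 1.0 + sum(
                amp * np.cos(k * th + ph) for amp, k, ph in zip(amps, ks, phases)
            )
            return p * f[..., None]

        ang = rng.uniform(-0.45, 0.45)
        sx, sy = rng.uniform(0.85, 1.15, 2)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        mat = rot @ np.diag([sx * scale_px, sy * scale_px])

        def fwd(p):
            return radial(p) @ mat.T

        outline_emb = fwd(template_contour)
        shift = -outline_emb.min(axis=0) + 20.0
        outline_emb = outline_emb + shift

        # each embryo's AFM grid is regular but placed with its own offset
        afm_tmpl_e = afm_template + rng.uniform(-0.2 * spacing, 0.2 * spacing, 2)
        afm_emb = fwd(afm_tmpl_e) + shift
        moduli = stiff_pa(afm_tmpl_e[:, ::-1]) + rng.normal(0, 8.0, len(afm_tmpl_e))
        afm = np.column_stack([afm_emb, moduli])

        # FM image over the embryo bounding box
        wpx = int(np.ceil(outline_emb[:, 0].max() + 20))
        hpx = int(np.ceil(outline_emb[:, 1].max() + 20))
        cols, rows_px = np.meshgrid(np.arange(wpx), np.arange(hpx))
        q = np.column_stack([cols.ravel() + 0.5, rows_px.ravel() + 0.5]) - shift
        inv = np.linalg.inv(mat)
        p_lin = q @ inv.T
        th = np.arctan2(p_lin[:, 1], p_lin[:, 0])
        f = 1.0 + sum(
            amp * np.cos(k * th + ph) for amp, k, ph in zip(amps, ks, phases)
        )
        p_tmpl = p_lin / f[:, None]
        in_brain = (p_tmpl[:, 0] / a_ax) ** 2 + (p_tmpl[:, 1] / b_ax) ** 2 <= 1.0
        img = np.full(hpx * wpx, 5.0)
        img[in_brain] = fm_intensity(p_tmpl[in_brain][:, ::-1])
        img = img.reshape(hpx, wpx) + rng.normal(0, 2.0, (hpx, wpx))

        samples.append(
            BrainSample(outline=outline_emb, afm_points=afm, fm_image=img, fm_pixel=1.0)
        )
        transforms.append({"amps": amps, "ks": ks, "phases": phases, "mat": mat, "shift": shift})
        for (tx, ty), m in zip(afm_template, moduli):
            rec_rows.append((e, tx, ty, m))

    records = pd.DataFrame(
        rec_rows, columns=["embryo", "template_x", "template_y", "modulus_pa"]
    )
    lat_pts = afm_template[:, ::-1]  # (y, x) ordering for the interpolators
    gt = GroundTruth(
        kind="brains",
        records=records,
        seed=seed,
        extras={
            "template_contour": template_contour,
            "afm_template": afm_template,
            "stiff_latent": np.asarray(stiff_pa(lat_pts)),
            "fm_latent": np.asarray(fm_intensity(lat_pts)),
            # field callables take (y, x) points in template coordinates
            "stiff_field": stiff_pa,
            "fm_field": fm_intensity,
            "transforms": transforms,
            "spacing": spacing,
        },
    )
    return samples, gt


# ---------------------------------------------------------------------------
# amplicon clones


BASES = np.array(list("ACGT"))


def make_amplicons(
    reference: str | None = None,
    p_edit: float = 0.3,
    n_clones: int = 20,
    vector_rate: float = 0.1,
    seed: int = 0,
    ref_length: int = 300,
):
    """Sanger-clone set around a cut site with Bernoulli per-clone editing.

    Each clone is vector-only with probability ``vector_rate``; otherwise it
    is edited with probability ``p_edit`` (edit type drawn uniformly from
    point mutation, multi-base mutation, insertion, deletion near the cut
    site) or clean.  Returns (Bio.SeqRecord list, truth).
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if not 0 <= p_edit <= 1 or not 0 <= vector_rate <= 1:
        raise ValueError("p_edit and vector_rate must be probabilities")
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = "".join(rng.choice(BASES, ref_length))
    reference = str(reference).upper()
    cut = len(reference) // 2
    vector = "".join(rng.choice(BASES, max(200, len(reference))))

    def mutate(kind: str) -> str:
        s = list(reference)
        if kind == "point_mutation":
            pos = cut + int(rng.integers(-5, 6))
            s[pos] = str(rng.choice([b for b in BASES if b != s[pos]]))
            return "".join(s)
        if kind == "multi_base":
            start = cut - 3
            for k in range(7):
                s[start + k] = str(rng.choice([b for b in BASES if b != s[start + k]]))
            return "".join(s)
        if kind == "insertion":
            ins = "".join(rng.choice(BASES, int(rng.integers(1, 6))))
            return reference[:cut] + ins + reference[cut:]
        if kind == "deletion":
            dlen = int(rng.integers(1, 9))
            return reference[:cut] + reference[cut + dlen :]
        raise AssertionError(kind)

    recs, rows = [], []
    kinds = ("point_mutation", "multi_base", "insertion", "deletion")
    for k in range(n_clones):
        cid = f"clone_{k:03d}"
        if rng.random() < vector_rate:
            seq, status = vector, "vector_only"
        elif rng.random() < p_edit:
            status = kinds[rng.integers(len(kinds))]
            seq = mutate(status)
        else:
            seq, status = reference, "clean"
        recs.append(SeqRecord(Seq(seq), id=cid, description=status))
        rows.append((cid, status))
    truth = pd.DataFrame(rows, columns=["clone_id", "status"])
    gt = GroundTruth(
        kind="amplicons", records=truth, seed=seed, extras={"reference": reference}
    )
    return recs, gt


# ---------------------------------------------------------------------------
# Sholl trees


def make_sholl_cell(
    n_primary_neurites: int = 4,
    branch_depth: int = 1,
    pixel_um: float = 0.5,
    image_size: int = 512,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Brightfield-like neurite image + nucleus channel with a known tree.

    Primary neurites leave the soma at well-separated angles and grow
    radially outward (each root-to-tip path crosses any circle at most
    once); branches split at ``branch_depth`` levels.  Returns
    (brightfield, nucleus_channel, truth); truth records every segment as
    (r0, c0, r1, c1) in pixel coordinates plus the centre.
    """
    if n_primary_neurites < 1:
        raise ValueError("need at least one neurite")
    rng = np.random.default_rng(seed)
    centre = np.array([image_size / 2.0, image_size / 2.0])  # (row, col)
    soma_r = 12.0
    circle_px = 10.0 / pixel_um  # Sholl circle pitch in px (radii at 2k*pitch/2)
    segments: list[tuple[float, float, float, float]] = []

    def snap_mid(radius: float) -> float:
        """Snap a radius to the midpoint between two Sholl circles.

        Branch points and tips sitting exactly on a counting circle are
        degenerate for any intersection definition; the generator keeps
        them half a pitch away.
        """
        return (round(radius / circle_px - 0.5) + 0.5) * circle_px

    def grow(start: np.ndarray, angle: float, target_r: float, depth: int,
             straight_px: float = 0.0) -> None:
        pos = start.copy()
        ang = angle
        seg_len = 18.0
        travelled = 0.0
        start_r = float(np.hypot(*(start - centre)))
        branch_r = snap_mid(start_r + 0.5 * (target_r - start_r)) if depth > 0 else np.inf
        if branch_r <= start_r + 15.0 or branch_r >= target_r - 15.0:
            branch_r = np.inf  # too close to an end point; grow unbranched
        while True:
            cur_r = float(np.hypot(*(pos - centre)))
            if cur_r >= target_r - 1.0:
                return
            if cur_r >= branch_r:
                grow(pos, ang + rng.uniform(0.45, 0.55), target_r, depth - 1,
                     straight_px=30.0)
                grow(pos, ang - rng.uniform(0.45, 0.55), target_r, depth - 1,
                     straight_px=30.0)
                return
            # daughters keep their split direction for a stretch so that
            # crossings with the next circle are well separated
            in_straight = travelled < straight_px
            if not in_straight:
                ang += rng.uniform(-0.10, 0.10)
            radial = np.arctan2(*(pos - centre))
            dev = np.angle(np.exp(1j * (ang - radial)))
            clamp = 0.7 if in_straight else 0.35
            if np.abs(dev) > clamp:
                ang = radial + np.sign(dev) * clamp
            step = min(seg_len, max(2.0, min(branch_r, target_r) - cur_r + 1.0))
            new = pos + np.array([np.sin(ang), np.cos(ang)]) * step
            segments.append((pos[0], pos[1], new[0], new[1]))
            pos = new
            travelled += step

    base = rng.uniform(0, 2 * np.pi)
    for i in range(n_primary_neurites):
        ang = base + 2 * np.pi * i / n_primary_neurites + rng.uniform(-0.15, 0.15)
        start = centre + np.array([np.sin(ang), np.cos(ang)]) * soma_r
        tip_r = snap_mid(rng.uniform(185.0, 220.0))
        grow(start, ang, tip_r, branch_depth)

    # rasterise: dark neurites on a bright background
    mask = np.zeros((image_size, image_size), dtype=bool)
    for r0, c0, r1, c1 in segments:
        npts = int(np.hypot(r1 - r0, c1 - c0) * 2) + 2
        rr = np.linspace(r0, r1, npts)
        cc = np.linspace(c0, c1, npts)
        ok = (rr >= 0) & (rr < image_size) & (cc >= 0) & (cc < image_size)
        mask[np.round(rr[ok]).astype(int), np.round(cc[ok]).astype(int)] = True
    mask = ndimage.binary_dilation(mask, iterations=1)
    rows_g, cols_g = np.indices((image_size, image_size))
    soma_mask = np.hypot(rows_g - centre[0], cols_g - centre[1]) <= soma_r
    bf = np.full((image_size, image_size), 200.0)
    bf[mask] = 120.0
    bf[soma_mask] = 110.0
    bf += rng.normal(0, 2.0, bf.shape)
    nucleus = np.zeros((image_size, image_size))
    nucleus[np.hypot(rows_g - centre[0], cols_g - centre[1]) <= 22.0] = 150.0
    nucleus += rng.normal(0, 2.0, nucleus.shape)

    truth = pd.DataFrame(segments, columns=["r0", "c0", "r1", "c1"])
    gt = GroundTruth(
        kind="sholl",
        records=truth,
        seed=seed,
        extras={"centre": tuple(centre), "soma_radius_px": soma_r, "pixel_um": pixel_um},
    )
    return bf, nucleus, gt
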