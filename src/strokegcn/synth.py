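"""Synthetic tennis-stroke generator.

Emulates the statistical structure the classifier assumes: four stroke
classes (forehand, backhand, volley forehand, volley backhand) recorded as
39 body markers plus a 7-marker rigid racket at 100 Hz, with variable trial
length, optical-jitter noise, ten subjects of whom one is left-handed, and
per-class trial counts matching the study corpus (backhand 212, forehand
197, volleys 180 each).

Kinematic model
---------------
The body is a fixed standing pose whose dominant arm chain is re-posed each
frame along a smooth azimuth sweep (a minimum-jerk-like smoothstep from a
backswing angle to a follow-through angle, with a height profile).  The
backhand is two-handed: the non-dominant arm follows the same hand target.
The racket is a rigid 7-point template moved by a single rigid transform
per frame; its roll about the shaft ("twist") distinguishes drives (the
face rolls over the ball) from volleys (the face stays open).

Where the class signal lives is controlled by ``racket_informative``:

- ``"both"`` (default): the forehand/backhand distinction is in the body
  (which arm swings, sweep direction) and the drive/volley distinction is
  in the racket twist only — the body paths of a drive and its volley are
  identical, mirroring how similar those movements are.  This makes the
  racket channels genuinely informative, the ground truth behind the
  with/without-racket ablation.
- ``"body_only"``: all four classes are separable from the body alone
  (volleys use a shorter, higher sweep) while the racket performs a generic
  swing whose transform is drawn independently of the class.
- ``"racket_only"``: the body performs a class-independent sway and only
  the (floating) racket follows the class-specific path.

Per-trial variability: amplitude and azimuth jitter, random duration, and
i.i.d. Gaussian coordinate noise (default 2 mm, typical optical jitter).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np

from .dataset import CLASS_NAMES, Trial, TrialSet
from .markers import load_marker_set

__all__ = [
    "SynthConfig",
    "StrokeTemplate",
    "generate_trial",
    "generate_dataset",
    "mirror_trial",
    "template_trajectory",
    "RACKET_LOCAL",
]

# Class-id order is (forehand, backhand, volley_forehand, volley_backhand);
# the default counts place 212 on backhand and 197 on forehand.
_DEFAULT_COUNTS = (197, 212, 180, 180)


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the defaults are the emulated study conditions."""

    counts: tuple[int, int, int, int] = _DEFAULT_COUNTS
    noise_sd: float = 2.0                       # mm, per coordinate
    duration_range: tuple[int, int] = (60, 180)  # frames at `rate`
    rate: float = 100.0                          # Hz
    n_subjects: int = 10
    n_left_handed: int = 1
    racket_informative: str = "both"             # both | body_only | racket_only
    seed: int = 0

    def __post_init__(self):
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.racket_informative not in ("both", "body_only", "racket_only"):
            raise ValueError(f"bad racket_informative {self.racket_informative!r}")
        if not (1 <= self.duration_range[0] <= self.duration_range[1]):
            raise ValueError("bad duration range")


# ---------------------------------------------------------------------------
# base pose (mm): x lateral (+ right), y forward (+ toward net), z up


def _mirror_x(p):
    return (-p[0], p[1], p[2])


_BASE_LEFT = {
    "LFHD": (-70, 60, 1650), "LBHD": (-75, -70, 1660),
    "LSHO": (-185, -30, 1440), "LUPA": (-225, -20, 1300),
    "LELB": (-255, -10, 1160), "LFRM": (-265, 30, 1050),
    "LWRA": (-275, 60, 960), "LWRB": (-305, 50, 950), "LFIN": (-285, 90, 895),
    "LASI": (-110, 80, 1000), "LPSI": (-60, -120, 1020),
    "LTHI": (-140, 40, 750), "LKNE": (-110, 20, 500), "LTIB": (-120, 40, 300),
    "LANK": (-90, 10, 90), "LHEE": (-80, -60, 40), "LTOE": (-90, 140, 30),
}
_BASE_POSE = dict(_BASE_LEFT)
_BASE_POSE.update({("R" + k[1:]): _mirror_x(v) for k, v in _BASE_LEFT.items()})
_BASE_POSE.update({
    "C7": (0, -80, 1500), "T10": (0, -110, 1250), "CLAV": (0, 40, 1450),
    "STRN": (0, 60, 1300), "RBAK": (90, -110, 1380),
})

# racket local frame: origin at head centre, z along shaft, x across the head
RACKET_LOCAL = {
    "RKT_TOP": (0.0, 0.0, 330.0),
    "RKT_SIDE_L1": (-120.0, 0.0, 250.0),
    "RKT_SIDE_L2": (-120.0, 0.0, 110.0),
    "RKT_SIDE_R1": (120.0, 0.0, 250.0),
    "RKT_SIDE_R2": (120.0, 0.0, 110.0),
    "RKT_HEAD_BOT": (0.0, 0.0, 60.0),
    "RKT_HANDLE": (0.0, 0.0, -330.0),
}


@dataclass(frozen=True)
class StrokeTemplate:
    """Per-class sweep parameters (azimuth in rad from +y, + toward +x)."""

    class_id: int
    az_start: float
    az_end: float
    reach: float          # mm, shoulder to hand
    z_start: float        # mm, hand height at backswing
    z_end: float          # mm, hand height at follow-through
    twist_start: float    # rad, racket roll about the shaft
    twist_end: float
    tilt_start: float     # rad, shaft tilt from vertical (0 = head straight up)
    tilt_end: float
    two_handed: bool


def _templates(mode: str) -> dict[int, StrokeTemplate]:
    # Drives sweep with the shaft laid well back and roll the face over;
    # volleys keep the head up with an open face (a short punch).  The
    # drive/volley contrast therefore lives in the racket *orientation*
    # (shaft tilt + roll), which displaces the whole marker cluster.
    fh = StrokeTemplate(0, 1.9, -1.2, 640, 900, 1180,
                        -1.4, 1.2, 1.9, 1.1, False)
    bh = StrokeTemplate(1, -1.9, 1.2, 640, 900, 1180,
                        1.4, -1.2, 1.9, 1.1, True)
    if mode == "body_only":
        # the volley distinction moves into the body: shorter, higher sweep
        vf = dc_replace(fh, class_id=2, az_start=1.2, az_end=-0.5,
                        z_start=1100, z_end=1330, twist_start=0.1,
                        twist_end=0.2, tilt_start=0.5, tilt_end=0.4)
        vb = dc_replace(bh, class_id=3, az_start=-1.2, az_end=0.5,
                        z_start=1100, z_end=1330, twist_start=-0.1,
                        twist_end=-0.2, tilt_start=0.5, tilt_end=0.4)
    else:
        # drive and volley bodies coincide; only the racket pose differs
        vf = dc_replace(fh, class_id=2, twist_start=0.1, twist_end=0.2,
                        tilt_start=0.5, tilt_end=0.4)
        vb = dc_replace(bh, class_id=3, twist_start=-0.1, twist_end=-0.2,
                        tilt_start=0.5, tilt_end=0.4)
    return {0: fh, 1: bh, 2: vf, 3: vb}


def _smoothstep(s: np.ndarray) -> np.ndarray:
    return s * s * (3.0 - 2.0 * s)


def _rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _pose_arm(sho: np.ndarray, az: float, hand_z: float, reach: float,
              side: str) -> dict[str, np.ndarray]:
    """Place the arm-chain markers for a hand target on the sweep."""
    dz = np.clip(hand_z - sho[2], -0.95 * reach, 0.95 * reach)
    r_h = np.sqrt(max(reach ** 2 - dz ** 2, 1.0))
    direction = np.array([np.sin(az), np.cos(az), 0.0])
    wrist = sho + r_h * direction + np.array([0.0, 0.0, dz])
    perp = np.array([direction[1], -direction[0], 0.0])
    bend = 60.0 * (1.0 if side == "R" else -1.0)
    elbow = sho + 0.5 * (wrist - sho) + bend * perp + np.array([0, 0, -40.0])
    out = {
        f"{side}UPA": sho + 0.55 * (elbow - sho),
        f"{side}ELB": elbow,
        f"{side}FRM": elbow + 0.6 * (wrist - elbow),
        f"{side}WRA": wrist + 27.0 * perp,
        f"{side}WRB": wrist - 27.0 * perp,
        f"{side}FIN": wrist + 70.0 * direction + np.array([0, 0, -20.0]),
    }
    return out


def _racket_frames(az: np.ndarray, twist: np.ndarray, tilt: np.ndarray,
                   anchor: np.ndarray) -> np.ndarray:
    """Rigidly place the racket template: one transform per frame.

    The shaft leans ``tilt`` rad away from vertical in the sweep direction,
    then rolls ``twist`` rad about its own axis; the handle marker tracks
    the anchor (the gripping hand).
    """
    local = np.array([RACKET_LOCAL[k] for k in load_marker_set("racket_7").names])
    T = az.shape[0]
    out = np.empty((T, local.shape[0], 3))
    for t in range(T):
        R = _rot_z(az[t]) @ _rot_x(tilt[t]) @ _rot_z(twist[t])
        handle_world = R @ np.array(RACKET_LOCAL["RKT_HANDLE"])
        out[t] = (local @ R.T) + (anchor[t] - handle_world)
    return out


_BODY_NAMES = load_marker_set("plug_in_gait_39").names
_RACKET_NAMES = load_marker_set("racket_7").names
_ALL_NAMES = _BODY_NAMES + _RACKET_NAMES


def _build_coords(template: StrokeTemplate, T: int, mode: str,
                  jitter: tuple[float, float] = (1.0, 0.0),
                  racket_params: tuple[float, float, float] | None = None
                  ) -> np.ndarray:
    """Noise-free 46-marker trajectory for one (right-handed) stroke.

    ``jitter`` is (amplitude scale, azimuth offset); ``racket_params``
    overrides the racket sweep (az_start, az_end, twist_amplitude) in the
    class-independent modes.
    """
    amp, az_off = jitter
    s = _smoothstep(np.linspace(0.0, 1.0, T))
    az = az_off + template.az_start + amp * s * (template.az_end - template.az_start)
    hand_z = template.z_start + s * (template.z_end - template.z_start)
    twist = template.twist_start + s * (template.twist_end - template.twist_start)
    tilt = template.tilt_start + s * (template.tilt_end - template.tilt_start)

    base = np.array([_BASE_POSE[k] for k in _BODY_NAMES], dtype=np.float64)
    coords = np.repeat(base[None], T, axis=0)
    idx = {k: i for i, k in enumerate(_BODY_NAMES)}

    if mode == "racket_only":
        # class-independent body: gentle forward sway only
        sway = 40.0 * np.sin(np.pi * s)
        coords[:, :, 1] += sway[:, None]
        dominant_wrist = coords[:, idx["RWRA"], :].copy()
    else:
        pelvis = base[[idx[k] for k in ("LASI", "RASI", "LPSI", "RPSI")]].mean(axis=0)
        trunk_rot = 0.25 * (az - az[len(az) // 2])
        torso = [idx[k] for k in ("LFHD", "RFHD", "LBHD", "RBHD", "C7", "T10",
                                  "CLAV", "STRN", "RBAK", "LSHO", "RSHO")]
        for t in range(T):
            R = _rot_z(trunk_rot[t])
            coords[t, torso] = (coords[t, torso] - pelvis) @ R.T + pelvis
        sway = 30.0 * np.sin(np.pi * s)
        coords[:, :, 1] += sway[:, None]

        sho_r = coords[:, idx["RSHO"], :]
        for t in range(T):
            for k, v in _pose_arm(sho_r[t], az[t], hand_z[t],
                                  template.reach, "R").items():
                coords[t, idx[k]] = v
        if template.two_handed:
            sho_l = coords[:, idx["LSHO"], :]
            for t in range(T):
                for k, v in _pose_arm(sho_l[t], az[t] - 0.12, hand_z[t] - 30.0,
                                      template.reach + 60.0, "L").items():
                    coords[t, idx[k]] = v
        dominant_wrist = 0.5 * (coords[:, idx["RWRA"], :] + coords[:, idx["RWRB"], :])

    if mode == "both":
        racket = _racket_frames(az, twist, tilt, dominant_wrist)
    elif mode == "body_only":
        # generic racket pendulum, transform drawn independently of class
        if racket_params is None:
            racket_params = (0.6, -0.6, 0.5, 1.2)
        r_az0, r_az1, r_twist, r_tilt = racket_params
        r_az = r_az0 + s * (r_az1 - r_az0)
        r_tw = r_twist * (2.0 * s - 1.0)
        anchor = np.repeat(np.array([[300.0, 350.0, 1000.0]]), T, axis=0)
        racket = _racket_frames(r_az, r_tw, np.full(T, r_tilt), anchor)
    else:  # racket_only: class-specific floating racket
        anchor = np.stack([500.0 * np.sin(az), 400.0 + 500.0 * np.cos(az),
                           np.full(T, 1000.0)], axis=1)
        racket = _racket_frames(az, twist, tilt, anchor)
    return np.concatenate([coords, racket], axis=1)


def template_trajectory(class_id: int, T: int = 100,
                        mode: str = "both") -> np.ndarray:
    """Deterministic noise-free class-mean trajectory (46 markers)."""
    if not 0 <= class_id < 4:
        raise ValueError(f"class id must be 0..3, got {class_id}")
    return _build_coords(_templates(mode)[class_id], T, mode)


# ---------------------------------------------------------------------------
# label mirroring (left-handed subjects)


def _mirror_label(name: str) -> str:
    if name.startswith("RKT_SIDE_L"):
        return "RKT_SIDE_R" + name[len("RKT_SIDE_L"):]
    if name.startswith("RKT_SIDE_R"):
        return "RKT_SIDE_L" + name[len("RKT_SIDE_R"):]
    if name.startswith("RKT_") or name == "RBAK":  # RBAK has no left twin
        return name
    if name[0] == "L":
        return "R" + name[1:]
    if name[0] == "R":
        return "L" + name[1:]
    return name


def mirror_trial(trial: Trial) -> Trial:
    """Reflect a trial across the sagittal plane (x -> -x).

    Left/right marker labels are swapped so the returned trial keeps the
    canonical marker order; handedness flips.  An involution and an
    isometry: inter-marker distances are preserved.
    """
    names = trial.marker_names
    perm = [names.index(_mirror_label(n)) for n in names]
    coords = trial.coords[:, perm, :].copy()
    coords[:, :, 0] *= -1.0
    return dc_replace(trial, coords=coords,
                      handedness="left" if trial.handedness == "right" else "right")


# ---------------------------------------------------------------------------
# public generation API


def generate_trial(class_id: int, cfg: SynthConfig,
                   rng: np.random.Generator) -> Trial:
    """Draw one synthetic 46-marker trial of the given class."""
    if not 0 <= class_id < len(CLASS_NAMES):
        raise ValueError(f"class id must be 0..3, got {class_id}")
    T = int(rng.integers(cfg.duration_range[0], cfg.duration_range[1] + 1))
    subject = int(rng.integers(cfg.n_subjects))
    left_handed = subject < cfg.n_left_handed
    jitter = (float(rng.normal(1.0, 0.05)), float(rng.normal(0.0, 0.03)))
    mode = cfg.racket_informative
    racket_params = None
    if mode == "body_only":
        # racket transform drawn independently of the class
        a0 = float(rng.uniform(-2.0, 2.0))
        racket_params = (a0, a0 + float(rng.uniform(-1.5, 1.5)),
                         float(rng.uniform(0.0, 1.0)),
                         float(rng.uniform(0.4, 1.9)))
    coords = _build_coords(_templates(mode)[class_id], T, mode,
                           jitter=jitter, racket_params=racket_params)
    if cfg.noise_sd > 0:
        coords = coords + rng.normal(0.0, cfg.noise_sd, coords.shape)
    trial = Trial(coords=coords, label=class_id, marker_names=_ALL_NAMES,
                  subject_id=f"S{subject:02d}",
                  handedness="right", rate=cfg.rate, source="synthetic")
    if left_handed:
        trial = mirror_trial(trial)
        trial.subject_id = f"S{subject:02d}"
    return trial


def generate_dataset(cfg: SynthConfig) -> TrialSet:
    """Generate the full labelled corpus described by ``cfg``.

    Fully reproducible from (cfg, cfg.seed); per-class counts equal
    ``cfg.counts`` in class-id order.
    """
    rng = np.random.default_rng(cfg.seed)
    trials = []
    for class_id, n in enumerate(cfg.counts):
        for _ in range(n):
            trials.append(generate_trial(class_id, cfg, rng))
    return TrialSet(trials)
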