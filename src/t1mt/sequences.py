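"""T1-mapping pulse-sequence protocols and signal simulation.

A protocol is an ordered list of events — RF pulses, free-precession delays,
readout markers, spoiler gradients and saturation blocks — possibly split into
several independent *acquisitions* (e.g. one per flip angle for variable flip
angle, one per inversion time for classic inversion recovery).  Each
acquisition is treated as one repetition cycle: by default the magnetization
is first driven to the periodic steady state of that cycle and the events are
then replayed once while the readout markers record the signal.

Event semantics
---------------
* ``rf``: full waveform propagation under the chosen spin model — the MT
  effect is simulated during *all* pulses (inversion, excitation, the
  saturation pulses of a saturation block are the exception below).
* ``delay``: free precession (relaxation + exchange).
* ``spoil``: ideal spoiling, zeroes the free-pool transverse components.
* ``saturate``: idealized saturation module (a crusher-interleaved train of
  90° pulses); destroys the magnetization of *both* pools.
* ``readout``: records the signal; ``record`` selects the convention —
  ``"z"`` (longitudinal free-pool magnetization, used where an idealized
  spin-echo/RARE readout samples zf), ``"mag"`` (transverse magnitude right
  after an excitation) or ``"signed"`` (transverse component projected on the
  excitation axis, keeps the sign of the pre-pulse longitudinal state).

Factory presets cover the three fully-specified in vivo protocols
(``invivo_ir``, ``invivo_vfa``, ``invivo_mp2rage``) and a 25-method
literature-like roster spanning the IR / SR / LL / vFA / MP-RAGE / MP2RAGE
families; roster parameters other than the in vivo three are representative
heuristics (``heuristic`` flag in the metadata).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

from .spin_models import (
    MODELS,
    RFPulse,
    SpinState,
    TwoPoolParameters,
    free_precession_propagator,
    hs1_pulse,
    pulse_propagator,
    rect_pulse,
)

__all__ = [
    "SequenceEvent",
    "Acquisition",
    "SequenceProtocol",
    "SimulatedSignal",
    "build_protocol",
    "simulate_signal",
    "periodic_steady_state",
    "preset",
    "preset_names",
    "invivo_protocols",
    "literature_roster",
]

FAMILIES = ("IR", "SR", "LL", "vFA", "MPRAGE", "MP2RAGE")


@dataclass(frozen=True)
class SequenceEvent:
    kind: str  # rf | delay | readout | spoil | saturate
    pulse: RFPulse | None = None
    duration: float = 0.0
    label: str = ""
    record: str = "z"  # z | mag | signed
    axis_phase: float = 0.0  # excitation axis for signed readouts


@dataclass(frozen=True)
class Repeat:
    """A readout-free block repeated ``count`` times (propagated with a
    matrix power instead of an explicit walk)."""

    events: tuple
    count: int

    @property
    def duration(self) -> float:
        return self.count * sum(e.duration for e in self.events)


@dataclass(frozen=True)
class Acquisition:
    events: tuple  # SequenceEvent | Repeat
    init: str = "steady_state"  # steady_state | equilibrium | zero


@dataclass(frozen=True)
class SequenceProtocol:
    """A T1-mapping method: events plus the identity of its fit procedure."""

    method_id: str
    family: str
    fit_procedure: str
    acquisitions: tuple
    meta: dict = field(default_factory=dict)

    def cache_key(self):
        return self.method_id

    @property
    def events(self):
        return tuple(
            e for acq in self.acquisitions for e in _flatten(acq.events)
        )

    @property
    def n_readouts(self):
        return sum(1 for e in self.events if e.kind == "readout")


@dataclass
class SimulatedSignal:
    """Readout samples: parallel arrays of label, time (s) and value."""

    labels: list
    times: np.ndarray
    values: np.ndarray

    def __getitem__(self, label):
        sel = [i for i, l in enumerate(self.labels) if l == label]
        if not sel:
            raise KeyError(label)
        return self.values[sel]

    def scaled(self, c):
        return SimulatedSignal(self.labels, self.times, self.values * c)


# ----------------------------------------------------------------------------
# protocol construction from a config mapping (the YAML/JSON schema)
# ----------------------------------------------------------------------------

_PULSE_SHAPES = ("rect", "hs1")


def _build_pulse(cfg: dict) -> RFPulse:
    shape = cfg.get("shape", "rect")
    if shape not in _PULSE_SHAPES:
        raise ValueError(f"unknown pulse shape {shape!r}")
    if shape == "rect":
        return rect_pulse(
            np.radians(cfg["flip_deg"]),
            cfg["duration_s"],
            phase=np.radians(cfg.get("phase_deg", 0.0)),
            frequency_offset=cfg.get("offset_hz", 0.0),
        )
    return hs1_pulse(
        duration=cfg.get("duration_s", 10e-3),
        bandwidth_hz=cfg.get("bandwidth_hz", 1200.0),
        adiabaticity=cfg.get("adiabaticity", 10.0),
        n_segments=cfg.get("n_segments", 48),
    )


def _flatten(events):
    for e in events:
        if isinstance(e, Repeat):
            for _ in range(e.count):
                yield from _flatten(e.events)
        else:
            yield e


def _expand_events(event_cfgs, last_pulse_phase=0.0):
    events = []
    phase = last_pulse_phase
    for cfg in event_cfgs:
        kind = cfg.get("type")
        if kind == "group":
            if "repeat" not in cfg or int(cfg["repeat"]) < 1:
                raise ValueError("group needs repeat >= 1")
            inner, phase = _expand_events(cfg["events"], phase)
            count = int(cfg["repeat"])
            if count > 1 and not any(
                e.kind == "readout" for e in _flatten(inner)
            ):
                events.append(Repeat(tuple(inner), count))
            else:
                events.extend(inner * count)
        elif kind == "rf":
            pulse = _build_pulse(cfg)
            phase = float(pulse.phase[0])
            events.append(SequenceEvent("rf", pulse=pulse, duration=pulse.duration))
        elif kind == "delay":
            d = float(cfg["duration_s"])
            if d < 0:
                raise ValueError(f"negative delay {d}")
            events.append(SequenceEvent("delay", duration=d))
        elif kind == "readout":
            events.append(
                SequenceEvent(
                    "readout",
                    label=cfg.get("label", f"s{len(events)}"),
                    record=cfg.get("record", "z"),
                    axis_phase=phase,
                )
            )
        elif kind == "spoil":
            events.append(SequenceEvent("spoil"))
        elif kind == "saturate":
            events.append(SequenceEvent("saturate"))
        else:
            raise ValueError(f"unknown event type {kind!r}")
    return events, phase


def build_protocol(config: dict) -> SequenceProtocol:
    """Build a :class:`SequenceProtocol` from a config mapping (the schema
    used by the YAML protocol files)."""
    for key in ("method_id", "family", "fit_procedure", "acquisitions"):
        if key not in config:
            raise ValueError(f"protocol config missing {key!r}")
    if config["family"] not in FAMILIES:
        raise ValueError(f"unknown family {config['family']!r}")
    acqs = []
    for acq_cfg in config["acquisitions"]:
        events, _ = _expand_events(acq_cfg["events"])
        if not events:
            raise ValueError("empty event list")
        has_source = False
        for e in _flatten(events):
            if e.kind in ("rf", "saturate"):
                has_source = True
            if e.kind == "readout" and not has_source:
                raise ValueError("readout before any rf/saturation event")
        acqs.append(
            Acquisition(tuple(events), init=acq_cfg.get("init", "steady_state"))
        )
    if not acqs:
        raise ValueError("protocol has no acquisitions")
    return SequenceProtocol(
        method_id=config["method_id"],
        family=config["family"],
        fit_procedure=config["fit_procedure"],
        acquisitions=tuple(acqs),
        meta=dict(config.get("meta", {})),
    )


# ----------------------------------------------------------------------------
# simulation
# ----------------------------------------------------------------------------

_SPOIL = np.diag([0.0, 0.0, 1.0, 1.0, 1.0])
_SATURATE = np.diag([0.0, 0.0, 0.0, 0.0, 1.0])


@functools.lru_cache(maxsize=16384)
def _free_prop(params: TwoPoolParameters, duration: float) -> np.ndarray:
    return free_precession_propagator(params, duration).matrix


def _event_matrix(event, params, model, b1):
    if isinstance(event, Repeat):
        uniq: dict = {}
        U = np.eye(5)
        for e in event.events:
            m = uniq.get(id(e))
            if m is None:
                m = _event_matrix(e, params, model, b1)
                uniq[id(e)] = m
            U = m @ U
        return np.linalg.matrix_power(U, event.count)
    if event.kind == "rf":
        pulse = event.pulse if b1 == 1.0 else event.pulse.scaled(b1)
        return pulse_propagator(params, pulse, model).matrix
    if event.kind == "delay":
        return _free_prop(params, event.duration)
    if event.kind == "spoil":
        return _SPOIL
    if event.kind == "saturate":
        return _SATURATE
    return None  # readout


def _cycle_fixed_point(mats):
    M = np.eye(5)
    for m in mats:
        if m is not None:
            M = m @ M
    L, b = M[:4, :4], M[:4, 4]
    A = np.eye(4) - L
    try:
        x = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError(
            "periodic steady state is singular (no relaxation in cycle?)"
        ) from exc
    if not np.all(np.isfinite(x)):
        raise RuntimeError("periodic steady state did not converge")
    vec = np.empty(5)
    vec[:4] = x
    vec[4] = 1.0
    return vec


def _record(event, vec):
    if event.record == "z":
        return vec[2]
    if event.record == "mag":
        return float(np.hypot(vec[0], vec[1]))
    if event.record == "signed":
        return float(
            -np.sin(event.axis_phase) * vec[0] + np.cos(event.axis_phase) * vec[1]
        )
    raise ValueError(f"unknown record convention {event.record!r}")


def simulate_signal(
    protocol: SequenceProtocol,
    params: TwoPoolParameters,
    model: str = "generalized_bloch",
    b1: float = 1.0,
) -> SimulatedSignal:
    """Simulate the readout samples of a protocol under a spin model.

    ``model`` is one of ``mono`` (semi-solid transparent to RF), ``graham``
    (spectral saturation-rate model) or ``generalized_bloch``.  ``b1`` scales
    every pulse amplitude (transmit-field factor).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model kind {model!r}")
    labels, times, values = [], [], []
    for acq in protocol.acquisitions:
        # event objects repeat heavily (readout trains); build each matrix once
        uniq: dict = {}
        mats = []
        for e in acq.events:
            m = uniq.get(id(e))
            if m is None and id(e) not in uniq:
                m = _event_matrix(e, params, model, b1)
                uniq[id(e)] = m
            mats.append(m)
        if acq.init == "steady_state":
            vec = _cycle_fixed_point(mats)
        elif acq.init == "equilibrium":
            vec = SpinState.equilibrium(params).to_vector()
        elif acq.init == "zero":
            vec = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
        else:
            raise ValueError(f"unknown init {acq.init!r}")
        t = 0.0
        for e, m in zip(acq.events, mats):
            if not isinstance(e, Repeat) and e.kind == "readout":
                labels.append(e.label)
                times.append(t)
                values.append(_record(e, vec))
            else:
                vec = m @ vec
                t += e.duration
    return SimulatedSignal(labels, np.asarray(times), np.asarray(values))


def periodic_steady_state(
    protocol: SequenceProtocol,
    params: TwoPoolParameters,
    model: str = "generalized_bloch",
    acquisition: int = 0,
    b1: float = 1.0,
) -> SpinState:
    """State ``s*`` with ``P(s*) = s*`` for one acquisition cycle.

    The cycle map is affine for every model (the semi-solid transverse
    response lives only inside pulse propagators), so the fixed point is a
    direct linear solve.
    """
    acq = protocol.acquisitions[acquisition]
    mats = [_event_matrix(e, params, model, b1) for e in acq.events]
    return SpinState.from_vector(_cycle_fixed_point(mats))


# ----------------------------------------------------------------------------
# vectorized mono-exponential simulation over a T1 grid
# (used to build MP2RAGE dictionaries; validated against simulate_signal)
# ----------------------------------------------------------------------------


def _rodrigues(axis, angle):
    n = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, n[2], -n[1]], [-n[2], 0, n[0]], [n[1], -n[0], 0]]
    )  # dM/dt = M x w convention
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def mono_signal_t1_grid(
    protocol: SequenceProtocol,
    t1_grid: np.ndarray,
    t2f: float = 76.9e-3,
    b1: float = 1.0,
):
    """Mono-exponential readout samples for every T1 in ``t1_grid`` at once.

    Pulses are propagated with Strang splitting (exact rotation about the
    per-segment effective field between exact half-interval relaxation
    steps), so the T1-independent rotation work is shared across the grid.
    Steady-state initialization extracts the cycle's affine map from four
    basis propagations and solves the fixed point exactly per grid point.
    """
    t1_grid = np.asarray(t1_grid, dtype=float)
    n = t1_grid.size

    def apply_events(state, record_to=None, evs=None):
        X, Y, Z = state
        for e in (events if evs is None else evs):
            if isinstance(e, Repeat):
                for _ in range(e.count):
                    X, Y, Z = apply_events((X, Y, Z), record_to, e.events)
                continue
            if e.kind == "delay":
                if e.duration > 0:
                    e2 = np.exp(-e.duration / t2f)
                    X, Y = X * e2, Y * e2
                    Z = 1.0 + (Z - 1.0) * np.exp(-e.duration / t1_grid)
            elif e.kind == "spoil":
                X, Y = np.zeros(n), np.zeros(n)
            elif e.kind == "saturate":
                X, Y, Z = np.zeros(n), np.zeros(n), np.zeros(n)
            elif e.kind == "rf":
                pulse = e.pulse if b1 == 1.0 else e.pulse.scaled(b1)
                dts, w1s, phis, wds = pulse.segments()
                for dt0, w1, phi0, wd in zip(dts, w1s, phis, wds):
                    # substeps keep the rotation/relaxation splitting error
                    # below ~1e-7
                    n_sub = max(1, int(np.ceil(dt0 / 10e-6)))
                    dt = dt0 / n_sub
                    h = 0.5 * dt
                    e2 = np.exp(-h / t2f)
                    e1 = np.exp(-h / t1_grid)
                    for k in range(n_sub):
                        phi = phi0 + wd * k * dt
                        X, Y, Z = X * e2, Y * e2, 1.0 + (Z - 1.0) * e1
                        w_eff = np.array(
                            [w1 * np.cos(phi), w1 * np.sin(phi), wd],
                            dtype=float,
                        )
                        ang = np.linalg.norm(w_eff) * dt
                        if ang > 0:
                            R = _rodrigues(w_eff, ang)
                            # restore the carrier frame after the ramp
                            c, s = np.cos(wd * dt), np.sin(wd * dt)
                            Rz = np.array(
                                [[c, -s, 0], [s, c, 0], [0, 0, 1.0]]
                            )
                            R = Rz @ R
                            X, Y, Z = (
                                R[0, 0] * X + R[0, 1] * Y + R[0, 2] * Z,
                                R[1, 0] * X + R[1, 1] * Y + R[1, 2] * Z,
                                R[2, 0] * X + R[2, 1] * Y + R[2, 2] * Z,
                            )
                        X, Y, Z = X * e2, Y * e2, 1.0 + (Z - 1.0) * e1
            elif e.kind == "readout" and record_to is not None:
                if e.record == "z":
                    record_to.append((e.label, Z.copy()))
                elif e.record == "mag":
                    record_to.append((e.label, np.hypot(X, Y)))
                else:
                    record_to.append(
                        (
                            e.label,
                            -np.sin(e.axis_phase) * X + np.cos(e.axis_phase) * Y,
                        )
                    )
        return X, Y, Z

    out: dict = {}
    for acq in protocol.acquisitions:
        events = acq.events
        if acq.init == "zero":
            state = (np.zeros(n), np.zeros(n), np.zeros(n))
        else:
            state = (np.zeros(n), np.zeros(n), np.ones(n))
            if acq.init == "steady_state":
                # cycle map is affine: M(s) = A s + c; recover A, c from
                # basis propagations and solve (I - A) s* = c exactly
                c = np.stack(
                    apply_events((np.zeros(n), np.zeros(n), np.zeros(n))),
                    axis=-1,
                )
                cols = []
                for j in range(3):
                    basis = [np.zeros(n), np.zeros(n), np.zeros(n)]
                    basis[j] = np.ones(n)
                    cols.append(
                        np.stack(apply_events(tuple(basis)), axis=-1) - c
                    )
                A = np.stack(cols, axis=-1)  # (n, 3, 3); A[:, i, j]
                lhs = np.eye(3)[None] - A
                sstar = np.linalg.solve(lhs, c[..., None])[..., 0]
                state = (sstar[:, 0], sstar[:, 1], sstar[:, 2])
        rec: list = []
        apply_events(state, record_to=rec)
        for label, vals in rec:
            out[label] = vals
    return out


# ----------------------------------------------------------------------------
# presets
# ----------------------------------------------------------------------------


def _rf(flip_deg, duration_s, **kw):
    return {"type": "rf", "shape": "rect", "flip_deg": flip_deg,
            "duration_s": duration_s, **kw}


def _hs1_cfg(**kw):
    return {"type": "rf", "shape": "hs1", **kw}


def _delay(d):
    return {"type": "delay", "duration_s": d}


def _readout(label, record):
    return {"type": "readout", "label": label, "record": record}


def _ir_satrec(method_id, td_s, ti_s, inv_dur, magnitude=True):
    """Saturation-prepared inversion recovery (the in vivo IR scheme): after
    each readout the magnetization of both pools is destroyed, recovers for
    TD, is inverted, recovers for TI, then a RARE readout samples zf."""
    events = []
    for i, (td, ti) in enumerate(zip(td_s, ti_s)):
        events += [
            {"type": "saturate"},
            _delay(td - inv_dur / 2),
            _rf(180.0, inv_dur),
            {"type": "spoil"},
            _delay(ti - inv_dur / 2),
            _readout(f"arm{i}", "z"),
        ]
    return build_protocol(
        {
            "method_id": method_id,
            "family": "IR",
            "fit_procedure": "ir",
            "acquisitions": [{"init": "steady_state", "events": events}],
            "meta": {
                "td_s": list(td_s),
                "ti_s": list(ti_s),
                "magnitude": magnitude,
            },
        }
    )


def _ir_classic(method_id, ti_s, tr_s, inv_dur, inv_shape="rect", exc_dur=100e-6,
                heuristic=True):
    """Classic inversion recovery: one acquisition per TI with repetition time
    TR; an idealized single-echo readout samples zf just before the 90-degree
    excitation (whose MT effect is simulated)."""
    acqs = []
    for i, ti in enumerate(ti_s):
        inv = (
            _hs1_cfg() if inv_shape == "hs1" else _rf(180.0, inv_dur)
        )
        inv_len = 10e-3 if inv_shape == "hs1" else inv_dur
        acqs.append(
            {
                "init": "steady_state",
                "events": [
                    inv,
                    {"type": "spoil"},
                    _delay(ti - inv_len / 2 - exc_dur / 2),
                    _readout(f"ti{i}", "z"),
                    _rf(90.0, exc_dur),
                    {"type": "spoil"},
                    _delay(tr_s - ti - inv_len / 2 - exc_dur / 2),
                ],
            }
        )
    return build_protocol(
        {
            "method_id": method_id,
            "family": "IR",
            "fit_procedure": "ir",
            "acquisitions": acqs,
            "meta": {"ti_s": list(ti_s), "magnitude": False, "heuristic": heuristic},
        }
    )


def _sr(method_id, t_s, exc_dur=100e-6):
    events = []
    for i, t in enumerate(t_s):
        events += [
            {"type": "saturate"},
            _delay(t - exc_dur / 2),
            _readout(f"t{i}", "z"),
            _rf(90.0, exc_dur),
            {"type": "spoil"},
            _delay(0.5),
        ]
    return build_protocol(
        {
            "method_id": method_id,
            "family": "SR",
            "fit_procedure": "sr",
            "acquisitions": [{"init": "steady_state", "events": events}],
            "meta": {"t_s": list(t_s), "heuristic": True},
        }
    )


def _ll(method_id, flip_deg, gap_s, n_samples, ti0_s, tail_s,
        inv_dur=50e-6, exc_dur=200e-6):
    """Look-Locker: inversion followed by a train of weak readout pulses.

    The published three-parameter fit plus the T1* correction is exact only
    in the weak-readout, full-relaxation limit (its residual bias is about
    -flip^2/4), so the presets use small flips and assume full recovery
    between repetitions (equilibrium initial state)."""
    unit = [
        _rf(flip_deg, exc_dur),
        _readout("s", "signed"),
        {"type": "spoil"},
        _delay(gap_s - exc_dur),
    ]
    events = [
        _rf(180.0, inv_dur),
        {"type": "spoil"},
        _delay(ti0_s - inv_dur / 2 - exc_dur / 2),
        {"type": "group", "repeat": n_samples, "events": unit},
        _delay(tail_s),
    ]
    t_s = [ti0_s + k * gap_s for k in range(n_samples)]
    return build_protocol(
        {
            "method_id": method_id,
            "family": "LL",
            "fit_procedure": "ll",
            "acquisitions": [{"init": "equilibrium", "events": events}],
            "meta": {
                "t_s": t_s,
                "flip_deg": flip_deg,
                "gap_s": gap_s,
                "heuristic": True,
            },
        }
    )


def _vfa(method_id, flips_deg, tr_s, exc_dur, heuristic=True):
    acqs = []
    for i, a in enumerate(flips_deg):
        acqs.append(
            {
                "init": "steady_state",
                "events": [
                    _rf(a, exc_dur),
                    _readout(f"fa{i}", "mag"),
                    _delay(tr_s - exc_dur),
                    {"type": "spoil"},
                ],
            }
        )
    return build_protocol(
        {
            "method_id": method_id,
            "family": "vFA",
            "fit_procedure": "vfa",
            "acquisitions": acqs,
            "meta": {
                "flips_deg": list(flips_deg),
                "tr_s": tr_s,
                "heuristic": heuristic,
            },
        }
    )


def _mprage(method_id, td_s, flip_deg, esp_s, n_train, k_center, cycle_s,
            inv_shape="rect", inv_dur=1e-3, exc_dur=100e-6):
    """MP-RAGE: inversion followed by one FLASH train; the sample at the
    k-space-center excitation (index ``k_center``) carries the contrast.  One
    acquisition per inversion delay; fitted like a classic IR series."""
    acqs, ti_eff = [], []
    inv_len = 10e-3 if inv_shape == "hs1" else inv_dur
    for i, td in enumerate(td_s):
        unit_pre = [
            _rf(flip_deg, exc_dur),
            {"type": "spoil"},
            _delay(esp_s - exc_dur),
        ]
        unit_ro = [
            _rf(flip_deg, exc_dur),
            _readout(f"ti{i}", "signed"),
            {"type": "spoil"},
            _delay(esp_s - exc_dur),
        ]
        events = [
            _hs1_cfg() if inv_shape == "hs1" else _rf(180.0, inv_dur),
            {"type": "spoil"},
            _delay(td - inv_len / 2),
        ]
        if k_center > 0:
            events.append({"type": "group", "repeat": k_center, "events": unit_pre})
        events.append({"type": "group", "repeat": 1, "events": unit_ro})
        rest = n_train - k_center - 1
        if rest > 0:
            events.append({"type": "group", "repeat": rest, "events": unit_pre})
        used = td + inv_len / 2 + n_train * esp_s
        events.append(_delay(cycle_s - used))
        acqs.append({"init": "steady_state", "events": events})
        ti_eff.append(td + (k_center + 0.5) * esp_s)
    return build_protocol(
        {
            "method_id": method_id,
            "family": "MPRAGE",
            "fit_procedure": "ir",
            "acquisitions": acqs,
            "meta": {"ti_s": ti_eff, "magnitude": False, "heuristic": True},
        }
    )


def _mp2rage(method_id, ti_s, tr_cycle_s, flips_deg, esp_s, n_train,
             exc_dur=100e-6, heuristic=True):
    """MP2RAGE: adiabatic inversion and two centric-ordered FLASH trains; the
    first excitation of each train (the k-space center) is recorded."""
    inv_len = 10e-3
    ti1, ti2 = ti_s
    d1 = ti1 - inv_len / 2 - exc_dur / 2
    train_len = n_train * esp_s
    d2 = (ti2 - ti1) - train_len
    d3 = tr_cycle_s - inv_len - d1 - 2 * train_len - d2
    if min(d1, d2, d3) < 0:
        raise ValueError("inconsistent MP2RAGE timing")

    def train(i, flip):
        first = [
            _rf(flip, exc_dur),
            _readout(f"ti{i}", "signed"),
            {"type": "spoil"},
            _delay(esp_s - exc_dur),
        ]
        rest = [_rf(flip, exc_dur), {"type": "spoil"}, _delay(esp_s - exc_dur)]
        return [
            {"type": "group", "repeat": 1, "events": first},
            {"type": "group", "repeat": n_train - 1, "events": rest},
        ]

    events = (
        [_hs1_cfg(), {"type": "spoil"}, _delay(d1)]
        + train(1, flips_deg[0])
        + [_delay(d2)]
        + train(2, flips_deg[1])
        + [_delay(d3)]
    )
    return build_protocol(
        {
            "method_id": method_id,
            "family": "MP2RAGE",
            "fit_procedure": "mp2rage",
            "acquisitions": [{"init": "steady_state", "events": events}],
            "meta": {
                "ti_s": list(ti_s),
                "tr_cycle_s": tr_cycle_s,
                "flips_deg": list(flips_deg),
                "heuristic": heuristic,
            },
        }
    )


_TI7 = [0.05, 0.1, 0.2, 0.4, 0.8, 1.6, 3.2]

_PRESET_FACTORIES = {
    # --- the three fully-printed in vivo protocols -------------------------
    "invivo_ir": lambda: _ir_satrec(
        "invivo_ir",
        td_s=[0.684, 4.171, 2.730, 0.010],
        ti_s=[0.015, 0.015, 0.278, 1.007],
        inv_dur=1e-3,
    ),
    "invivo_vfa": lambda: _vfa(
        "invivo_vfa", [4.0, 25.0], tr_s=21e-3, exc_dur=100e-6, heuristic=False
    ),
    "invivo_mp2rage": lambda: _mp2rage(
        "invivo_mp2rage",
        ti_s=[0.92, 2.88],
        tr_cycle_s=5.0,
        flips_deg=[4.0, 5.0],
        esp_s=7.08e-3,
        n_train=192,
        heuristic=False,
    ),
    # --- inversion recovery ------------------------------------------------
    "ir_se_7ti": lambda: _ir_classic("ir_se_7ti", _TI7, 10.0, 1e-3),
    "ir_hard_10us": lambda: _ir_classic("ir_hard_10us", _TI7, 10.0, 10e-6),
    "ir_adiabatic": lambda: _ir_classic(
        "ir_adiabatic", _TI7, 10.0, 1e-3, inv_shape="hs1"
    ),
    "ir_long_ti": lambda: _ir_classic(
        "ir_long_ti", [0.3, 0.6, 1.2, 2.4, 4.8], 12.0, 1e-3
    ),
    "ir_short_ti": lambda: _ir_classic(
        "ir_short_ti", [0.03, 0.06, 0.12, 0.25, 0.5, 1.0], 8.0, 0.5e-3
    ),
    "ir_satrec_b": lambda: _ir_satrec(
        "ir_satrec_b",
        td_s=[0.5, 3.0, 2.0, 0.010],
        ti_s=[0.020, 0.020, 0.250, 0.900],
        inv_dur=1e-3,
    ),
    "ir_2ms": lambda: _ir_classic("ir_2ms", [0.1, 0.3, 0.9, 2.7], 9.0, 2e-3),
    # --- saturation recovery ----------------------------------------------
    "sr_4pt": lambda: _sr("sr_4pt", [0.1, 0.3, 0.9, 2.7]),
    "sr_5pt": lambda: _sr("sr_5pt", [0.15, 0.4, 1.0, 3.0, 6.0]),
    # --- Look-Locker -------------------------------------------------------
    "ll_3deg": lambda: _ll("ll_3deg", 3.0, 0.15, 30, 0.015, 2.0),
    "ll_2p5deg": lambda: _ll("ll_2p5deg", 2.5, 0.12, 35, 0.012, 2.5),
    "ll_2deg": lambda: _ll("ll_2deg", 2.0, 0.20, 22, 0.010, 1.5),
    # --- variable flip angle ----------------------------------------------
    "vfa_tr15": lambda: _vfa("vfa_tr15", [3.0, 17.0], 15e-3, 100e-6),
    "vfa_tr30": lambda: _vfa("vfa_tr30", [5.0, 26.0], 30e-3, 150e-6),
    "vfa_3fa": lambda: _vfa("vfa_3fa", [2.0, 9.0, 19.0], 18e-3, 100e-6),
    "vfa_tr25": lambda: _vfa("vfa_tr25", [4.0, 23.0], 25e-3, 120e-6),
    "vfa_tr12": lambda: _vfa("vfa_tr12", [3.0, 14.0], 12e-3, 70e-6),
    "vfa_tr40": lambda: _vfa("vfa_tr40", [5.0, 28.0], 40e-3, 150e-6),
    "vfa_tr20": lambda: _vfa("vfa_tr20", [6.0, 32.0], 20e-3, 100e-6),
    # --- MP-RAGE -----------------------------------------------------------
    "mprage_linear": lambda: _mprage(
        "mprage_linear", [0.2, 0.6, 1.2, 2.5], 8.0, 10e-3, 64, 32, 6.0
    ),
    "mprage_centric": lambda: _mprage(
        "mprage_centric", [0.25, 0.75, 1.8, 3.5], 9.0, 8e-3, 80, 0, 6.0,
        inv_shape="hs1",
    ),
    # --- MP2RAGE -----------------------------------------------------------
    "mp2rage_b": lambda: _mp2rage(
        "mp2rage_b",
        ti_s=[0.8, 2.2],
        tr_cycle_s=6.0,
        flips_deg=[5.0, 6.0],
        esp_s=6.5e-3,
        n_train=160,
    ),
}


@functools.lru_cache(maxsize=None)
def preset(name: str) -> SequenceProtocol:
    """Protocol preset by name (see :func:`preset_names`)."""
    try:
        return _PRESET_FACTORIES[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name!r}") from None


def preset_names():
    return sorted(_PRESET_FACTORIES)


def invivo_protocols():
    """The three fully-specified in vivo protocols."""
    return [preset(n) for n in ("invivo_ir", "invivo_mp2rage", "invivo_vfa")]


def literature_roster():
    """The 25-method literature-like roster (all presets)."""
    return [preset(n) for n in preset_names()]
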