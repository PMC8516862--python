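"""Construction of the control microcircuit and its SCZ-like variants.

The network couples 20 excitatory pyramidal cells and 10 inhibitory PV+
basket cells all-to-all (within and between populations), plus a single
pacemaker drive source. Three schizophrenia-associated alterations are
modelled on top of the control circuit:

* ``IPSC`` — prolonged inhibition: the inhibitory decay time constant is
  raised from 8 to 28 ms (reduced GAT1 reuptake).
* ``gGABA`` — reduced GABA levels: the inhibitory weights ``g_ie`` and
  ``g_ii`` are scaled down by a fraction.
* ``bInh`` — NMDAR hypofunction at interneurons: the applied current of
  inhibitory cells is decremented (they become less excitable).

The four named variants are ``control``, ``IPSC``, ``IPSC+gGABA``,
``IPSC+bInh`` and ``Full`` (all three alterations combined).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import ModelParameters

VARIANTS = ("control", "IPSC", "IPSC+gGABA", "IPSC+bInh", "Full")

#: inhibitory decay time constant (ms) under the prolonged-IPSC alteration
TAU_INH_ALTERED = 28.0


@dataclass
class NetworkModel:
    """Resolved synaptic structure of one network instance.

    Arrays are indexed (presynaptic, postsynaptic); presynaptic rows run
    over E cells, then I cells, then the pacemaker (last row). ``alpha``
    holds the sign of each presynaptic cell's synapses (+1 excitatory and
    pacemaker, -1 inhibitory); ``tau_mat`` the per-synapse decay time.
    """

    n_E: int
    n_I: int
    weights: np.ndarray
    alpha: np.ndarray
    tau_mat: np.ndarray
    b_per_cell: np.ndarray
    variant_label: str
    gGABA_level: float
    bInh_decrement: float
    params: ModelParameters

    @property
    def n_cells(self) -> int:
        return self.n_E + self.n_I

    def copy(self) -> "NetworkModel":
        return NetworkModel(
            n_E=self.n_E,
            n_I=self.n_I,
            weights=self.weights.copy(),
            alpha=self.alpha.copy(),
            tau_mat=self.tau_mat.copy(),
            b_per_cell=self.b_per_cell.copy(),
            variant_label=self.variant_label,
            gGABA_level=self.gGABA_level,
            bInh_decrement=self.bInh_decrement,
            params=self.params,
        )


def build_network(
    variant: str,
    params: ModelParameters | None = None,
    gGABA_level: float = 1.0,
    bInh_level: float = 0.0,
    autapses: bool = True,
    ipsc_onto_E_only: bool = False,
    binh_semantics: str = "absolute",
    tau_inh_altered: float = TAU_INH_ALTERED,
) -> NetworkModel:
    """Build the control network or one of the SCZ-like variants.

    Parameters
    ----------
    variant:
        One of ``control``, ``IPSC``, ``IPSC+gGABA``, ``IPSC+bInh``,
        ``Full``.
    gGABA_level:
        Fraction of the control inhibitory weights retained (1.0 = control
        strength); only applied by the ``+gGABA`` and ``Full`` variants.
    bInh_level:
        Magnitude of the interneuron-excitability alteration; only applied
        by the ``+bInh`` and ``Full`` variants. With the default
        ``absolute`` semantics the inhibitory applied current becomes
        ``-bInh_level`` (so the mildest swept value, 0.01, reproduces the
        control current exactly); with ``decrement`` it becomes
        ``b - bInh_level``.
    autapses:
        Include self-synapses within each population (all-to-all including
        the diagonal). Set False to exclude them for sensitivity checks.
    ipsc_onto_E_only:
        Alternative reading of the prolonged-IPSC alteration in which only
        I->E synapses are slowed; the default slows all inhibitory
        synapses.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if params is None:
        params = ModelParameters()
    if not (0.0 < gGABA_level <= 1.0):
        raise ValueError("gGABA_level must be in (0, 1]")
    if binh_semantics not in ("decrement", "absolute"):
        raise ValueError("binh_semantics must be 'decrement' or 'absolute'")

    n_E, n_I = params.n_E, params.n_I
    n = n_E + n_I
    use_ipsc = variant != "control"
    use_ggaba = variant in ("IPSC+gGABA", "Full")
    use_binh = variant in ("IPSC+bInh", "Full")

    g_ie = params.g_ie * (gGABA_level if use_ggaba else 1.0)
    g_ii = params.g_ii * (gGABA_level if use_ggaba else 1.0)

    weights = np.zeros((n + 1, n))
    weights[:n_E, :n_E] = params.g_ee
    weights[:n_E, n_E:] = params.g_ei
    weights[n_E:n, :n_E] = g_ie
    weights[n_E:n, n_E:] = g_ii
    weights[n, :n_E] = params.I_factor * params.g_de
    weights[n, n_E:] = params.I_factor * params.g_di
    if not autapses:
        np.fill_diagonal(weights[:n, :n], 0.0)

    alpha = np.ones(n + 1)
    alpha[n_E:n] = -1.0

    tau_inh = tau_inh_altered if use_ipsc else params.tau_inh
    tau_mat = np.full((n + 1, n), params.tau_exc)
    tau_mat[n_E:n, :] = tau_inh
    if use_ipsc and ipsc_onto_E_only:
        tau_mat[n_E:n, n_E:] = params.tau_inh

    b_per_cell = np.full(n, params.b)
    if use_binh and bInh_level == 0 and params.b_inh_delta == 0:
        raise ValueError(f"variant {variant!r} requires a nonzero bInh_level")
    if use_binh:
        dec = abs(bInh_level) + abs(params.b_inh_delta)
        if binh_semantics == "decrement":
            b_per_cell[n_E:] = params.b - dec
        else:
            b_per_cell[n_E:] = -dec
    elif params.b_inh_delta:
        b_per_cell[n_E:] = params.b - abs(params.b_inh_delta)

    return NetworkModel(
        n_E=n_E,
        n_I=n_I,
        weights=weights,
        alpha=alpha,
        tau_mat=tau_mat,
        b_per_cell=b_per_cell,
        variant_label=variant,
        gGABA_level=gGABA_level if use_ggaba else 1.0,
        bInh_decrement=abs(bInh_level) if use_binh else 0.0,
        params=params,
    )


def scale_input(network: NetworkModel, I_factor: float) -> NetworkModel:
    """Return a copy with the pacemaker weights set to ``I_factor * g_d*``.

    Only the two pacemaker weight groups change; every other synapse is
    untouched.
    """
    if I_factor <= 0:
        raise ValueError("I_factor must be > 0")
    out = network.copy()
    p = network.params
    out.weights[-1, : network.n_E] = I_factor * p.g_de
    out.weights[-1, network.n_E:] = I_factor * p.g_di
    out.params = p.with_(I_factor=I_factor)
    return out


def _binh_grid() -> list[float]:
    # -0.01 .. -0.10 in steps of -0.01, then -0.15 .. -0.60 in steps of -0.05
    first = [round(0.01 * i, 2) for i in range(1, 11)]
    second = [round(0.15 + 0.05 * i, 2) for i in range(0, 10)]
    return first + second


def alteration_grid(variant: str) -> list[tuple[float, float]]:
    """The (gGABA_level, bInh_level) sweep grid of each variant family.

    ``IPSC+gGABA``: inhibitory weights from 100% down to 10% in 5% steps.
    ``IPSC+bInh``: excitability decrements 0.01..0.10 (step 0.01) then
    0.15..0.60 (step 0.05). ``Full``: 10 gGABA levels (step 10%) paired
    one-to-one with a 10-point subsample of the bInh grid spanning its full
    range.
    """
    if variant == "IPSC+gGABA":
        levels = [round(1.0 - 0.05 * i, 2) for i in range(19)]  # 1.00 .. 0.10
        return [(lvl, 0.0) for lvl in levels]
    if variant == "IPSC+bInh":
        return [(1.0, d) for d in _binh_grid()]
    if variant == "Full":
        glevels = [round(1.0 - 0.1 * i, 1) for i in range(10)]  # 1.0 .. 0.1
        full_b = _binh_grid()
        bsub = [full_b[i] for i in (0, 2, 4, 6, 8, 10, 12, 14, 16, 19)]
        return list(zip(glevels, bsub))
    raise ValueError(
        f"no alteration grid for variant {variant!r}; "
        "expected IPSC+gGABA, IPSC+bInh or Full"
    )
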