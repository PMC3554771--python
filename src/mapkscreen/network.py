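"""Generic three-tier MAPK cascade as an elementary mass-action reaction network.

The cascade couples an input species (a pseudo-molecular stimulus carrier in
an active/inactive equilibrium) to the canonical MAPKKK -> MAPKK -> MAPK
phosphorylation chain.  MAPKKK is activated in a single step by the active
input; MAPKK and MAPK are each activated by *distributive* dual
phosphorylation (two independent enzyme-substrate collisions) and
deactivated by their cognate phosphatases (M2KP and MKP) through the same
two-step mechanism.  Every enzyme-catalyzed conversion is split into a
reversible binding step and an irreversible catalytic step, so
enzyme-substrate complexes are explicit species and competitive
sequestration of shared enzymes and substrates is represented.

All quantities are in relative units: [MAPKKK]_total = 1 sets the
concentration scale and the MAPKKK-activation catalytic constant (fixed at
1 and therefore not a free parameter) sets the time scale.

The network has 20 species and 28 free rate constants.  An optional
feedback from free pp-MAPK onto the input carries a single magnitude ``kf``:
positive feedback accelerates input activation, negative feedback
accelerates input inactivation; the two are never combined.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Topology",
    "KineticRates",
    "ConcentrationVector",
    "Reaction",
    "ReactionNetwork",
    "build_network",
    "rhs",
    "jacobian",
    "rhs_brute_force",
    "SPECIES",
    "RATE_NAMES",
    "UnknownTopologyError",
    "InvalidStateError",
]


class UnknownTopologyError(ValueError):
    """Raised when a topology selector is not one of none/positive/negative."""


class InvalidStateError(ValueError):
    """Raised when a state or rate vector violates nonnegativity."""


class Topology(enum.Enum):
    """Feedback wiring of the cascade.

    ``POSITIVE``: free pp-MAPK accelerates input activation.
    ``NEGATIVE``: free pp-MAPK accelerates input inactivation.
    ``NONE``: no feedback (``kf`` must be 0).
    """

    NONE = "none"
    POSITIVE = "positive"
    NEGATIVE = "negative"

    @classmethod
    def coerce(cls, value: "Topology | str") -> "Topology":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise UnknownTopologyError(
                f"unknown topology {value!r}; expected one of "
                f"{[t.value for t in cls]}"
            ) from None


#: Canonical species ordering.  ``*`` marks the active MAPKKK form, ``p-`` /
#: ``pp-`` mark mono- and dual-phosphorylation, ``:`` joins enzyme-substrate
#: complexes (enzyme first).
SPECIES: tuple[str, ...] = (
    "Input_inactive",      # 0
    "Input_active",        # 1
    "MAPKKK",              # 2
    "MAPKKK*",             # 3
    "MAPKK",               # 4
    "p-MAPKK",             # 5
    "pp-MAPKK",            # 6
    "MAPK",                # 7
    "p-MAPK",              # 8
    "pp-MAPK",             # 9
    "M2KP",                # 10
    "MKP",                 # 11
    "MAPKKK*:MAPKK",       # 12
    "MAPKKK*:p-MAPKK",     # 13
    "M2KP:pp-MAPKK",       # 14
    "M2KP:p-MAPKK",        # 15
    "pp-MAPKK:MAPK",       # 16
    "pp-MAPKK:p-MAPK",     # 17
    "MKP:pp-MAPK",         # 18
    "MKP:p-MAPK",          # 19
)

SPECIES_INDEX = {name: i for i, name in enumerate(SPECIES)}

#: The 28 free rate-constant names.  The MAPKKK-activation catalytic
#: constant is fixed at 1 (it defines the time unit) and is excluded.
RATE_NAMES: tuple[str, ...] = (
    "ka_in", "ki_in", "kf", "k-1",
    "kb2", "kd2", "k2",        # MAPKKK* + MAPKK   -> p-MAPKK
    "kb3", "kd3", "k3",        # MAPKKK* + p-MAPKK -> pp-MAPKK
    "kb-3", "kd-3", "k-3",     # M2KP + pp-MAPKK   -> p-MAPKK
    "kb-2", "kd-2", "k-2",     # M2KP + p-MAPKK    -> MAPKK
    "kb4", "kd4", "k4",        # pp-MAPKK + MAPK   -> p-MAPK
    "kb5", "kd5", "k5",        # pp-MAPKK + p-MAPK -> pp-MAPK
    "kb-5", "kd-5", "k-5",     # MKP + pp-MAPK     -> p-MAPK
    "kb-4", "kd-4", "k-4",     # MKP + p-MAPK      -> MAPK
)

#: Internal name of the fixed MAPKKK-activation constant (value locked to 1).
FIXED_ACTIVATION = "k1(fixed)"


@dataclass(frozen=True)
class KineticRates:
    """The 28 named nonnegative rate constants, in relative units.

    ``values`` maps every name in :data:`RATE_NAMES` to a float.  ``kf`` is
    the shared feedback magnitude; it must be exactly 0 for the no-feedback
    topology.
    """

    values: dict[str, float]

    def __post_init__(self):
        missing = set(RATE_NAMES) - set(self.values)
        extra = set(self.values) - set(RATE_NAMES)
        if missing or extra:
            raise KeyError(
                f"rate vector must name exactly the 28 constants; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        for name, v in self.values.items():
            if not np.isfinite(v) or v < 0:
                raise InvalidStateError(f"rate {name} = {v!r} must be finite and >= 0")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    @property
    def kf(self) -> float:
        return self.values["kf"]

    def with_kf(self, kf: float) -> "KineticRates":
        return KineticRates({**self.values, "kf": float(kf)})

    def replace(self, **updates: float) -> "KineticRates":
        vals = dict(self.values)
        for name, v in updates.items():
            key = name.replace("m", "-") if name not in RATE_NAMES else name
            if key not in RATE_NAMES:
                raise KeyError(name)
            vals[key] = float(v)
        return KineticRates(vals)

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in RATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "KineticRates":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(RATE_NAMES),):
            raise ValueError(f"expected {len(RATE_NAMES)} rates, got {arr.shape}")
        return cls(dict(zip(RATE_NAMES, arr.tolist())))

    def validate_topology(self, topology: Topology | str) -> None:
        topology = Topology.coerce(topology)
        if topology is Topology.NONE and self.kf != 0.0:
            raise InvalidStateError(
                f"no-feedback topology requires kf = 0, got kf = {self.kf}"
            )


@dataclass(frozen=True)
class ConcentrationVector:
    """Total amounts of the four variable pools, relative to [MAPKKK]_total = 1.

    [MAPKKK]_total and [Input]_total are fixed at 1.  All phosphorylated and
    complexed species start at zero, so the quiescent initial state is fully
    determined by the four totals.
    """

    mapkk: float
    mapk: float
    m2kp: float
    mkp: float

    def __post_init__(self):
        for name in ("mapkk", "mapk", "m2kp", "mkp"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidStateError(f"total {name} = {v!r} must be finite and > 0")

    mapkkk: float = field(default=1.0, init=False, repr=False)
    input_total: float = field(default=1.0, init=False, repr=False)

    def quiescent_state(self) -> np.ndarray:
        """Initial state: free unmodified pools only."""
        x = np.zeros(len(SPECIES))
        x[SPECIES_INDEX["Input_inactive"]] = self.input_total
        x[SPECIES_INDEX["MAPKKK"]] = self.mapkkk
        x[SPECIES_INDEX["MAPKK"]] = self.mapkk
        x[SPECIES_INDEX["MAPK"]] = self.mapk
        x[SPECIES_INDEX["M2KP"]] = self.m2kp
        x[SPECIES_INDEX["MKP"]] = self.mkp
        return x

    def totals(self) -> np.ndarray:
        """Moiety totals in the order of :func:`conservation_vectors`."""
        return np.array(
            [self.input_total, self.mapkkk, self.mapkk, self.mapk, self.m2kp, self.mkp]
        )

    def replace_mapkk(self, mapkk: float) -> "ConcentrationVector":
        return ConcentrationVector(mapkk, self.mapk, self.m2kp, self.mkp)


@dataclass(frozen=True)
class Reaction:
    """One elementary uni- or bimolecular mass-action reaction.

    ``rate_species`` are the species indices whose concentrations multiply
    the rate constant (reactants plus any catalytic modifier);
    ``stoich`` maps species index -> signed stoichiometric change.
    ``stimulus_scaled`` marks the input-activation step whose effective
    constant is ``ka_in * S``.
    """

    name: str
    rate_constant: str
    rate_species: tuple[int, ...]
    stoich: dict[int, int]
    stimulus_scaled: bool = False

    def __post_init__(self):
        if not 1 <= len(self.rate_species) <= 2:
            raise ValueError("elementary reactions are uni- or bimolecular")


def _cycle(label: str, enzyme: str, substrate: str, complex_: str, product: str,
           kb: str, kd: str, kcat: str) -> list[Reaction]:
    """Binding / dissociation / catalysis triplet for one conversion."""
    e, s, c, p = (SPECIES_INDEX[n] for n in (enzyme, substrate, complex_, product))
    return [
        Reaction(f"{label} binding", kb, (e, s), {e: -1, s: -1, c: +1}),
        Reaction(f"{label} dissociation", kd, (c,), {c: -1, e: +1, s: +1}),
        Reaction(f"{label} catalysis", kcat, (c,), {c: -1, e: +1, p: +1}),
    ]


def conservation_vectors() -> np.ndarray:
    """The six moiety-conservation vectors, one row per conserved pool.

    Rows: Input, MAPKKK, MAPKK, MAPK, M2KP, MKP.  Each counts the pool's
    free, modified and complexed forms.
    """
    C = np.zeros((6, len(SPECIES)))
    moieties = {
        0: ["Input_inactive", "Input_active"],
        1: ["MAPKKK", "MAPKKK*", "MAPKKK*:MAPKK", "MAPKKK*:p-MAPKK"],
        2: ["MAPKK", "p-MAPKK", "pp-MAPKK", "MAPKKK*:MAPKK", "MAPKKK*:p-MAPKK",
            "M2KP:pp-MAPKK", "M2KP:p-MAPKK", "pp-MAPKK:MAPK", "pp-MAPKK:p-MAPK"],
        3: ["MAPK", "p-MAPK", "pp-MAPK", "pp-MAPKK:MAPK", "pp-MAPKK:p-MAPK",
            "MKP:pp-MAPK", "MKP:p-MAPK"],
        4: ["M2KP", "M2KP:pp-MAPKK", "M2KP:p-MAPKK"],
        5: ["MKP", "MKP:pp-MAPK", "MKP:p-MAPK"],
    }
    for row, names in moieties.items():
        for n in names:
            C[row, SPECIES_INDEX[n]] = 1.0
    return C


MOIETY_NAMES = ("Input", "MAPKKK", "MAPKK", "MAPK", "M2KP", "MKP")


@dataclass(frozen=True)
class ReactionNetwork:
    """Assembled cascade: species list, reaction list, stoichiometry matrix.

    ``stoichiometry`` has shape (n_species, n_reactions).  The arrays
    ``_idx_a`` / ``_idx_b`` give, per reaction, the one or two species whose
    concentrations enter the mass-action rate (``-1`` when unimolecular);
    ``_k_index`` maps each reaction to its slot in the 28-vector of rate
    constants (``-1`` for the fixed MAPKKK-activation step).
    """

    topology: Topology
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    stoichiometry: np.ndarray
    conservation: np.ndarray
    _idx_a: np.ndarray
    _idx_b: np.ndarray
    _k_index: np.ndarray
    _stim_mask: np.ndarray

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def rate_names(self) -> tuple[str, ...]:
        return RATE_NAMES

    def effective_constants(self, rates: KineticRates, S: float) -> np.ndarray:
        """Per-reaction effective rate constants at stimulus strength S."""
        if S < 0:
            raise InvalidStateError(f"stimulus S = {S} must be >= 0")
        kvec = rates.as_array()
        k = np.where(self._k_index >= 0, kvec[self._k_index], 1.0)
        return np.where(self._stim_mask, k * S, k)


def build_network(topology: Topology | str) -> ReactionNetwork:
    """Assemble the 20-species, 28-rate cascade for a feedback topology.

    The reaction list always contains one feedback reaction carrying ``kf``:
    for the positive topology (and, with ``kf`` pinned to 0, the no-feedback
    topology) it adds to input activation; for the negative topology it adds
    to input inactivation.  With ``kf = 0`` all three wirings therefore have
    identical dynamics.
    """
    topology = Topology.coerce(topology)
    ix = SPECIES_INDEX
    ii, ia = ix["Input_inactive"], ix["Input_active"]
    k3, k3a = ix["MAPKKK"], ix["MAPKKK*"]
    ppk = ix["pp-MAPK"]

    reactions: list[Reaction] = [
        Reaction("input activation", "ka_in", (ii,), {ii: -1, ia: +1},
                 stimulus_scaled=True),
        Reaction("input inactivation", "ki_in", (ia,), {ia: -1, ii: +1}),
    ]
    if topology is Topology.NEGATIVE:
        reactions.append(
            Reaction("feedback (pp-MAPK -> input inactivation)", "kf",
                     (ppk, ia), {ia: -1, ii: +1})
        )
    else:
        reactions.append(
            Reaction("feedback (pp-MAPK -> input activation)", "kf",
                     (ppk, ii), {ii: -1, ia: +1})
        )
    reactions += [
        Reaction("MAPKKK activation", FIXED_ACTIVATION, (ia, k3), {k3: -1, k3a: +1}),
        Reaction("MAPKKK inactivation", "k-1", (k3a,), {k3a: -1, k3: +1}),
    ]
    reactions += _cycle("MAPKK P1", "MAPKKK*", "MAPKK", "MAPKKK*:MAPKK",
                        "p-MAPKK", "kb2", "kd2", "k2")
    reactions += _cycle("MAPKK P2", "MAPKKK*", "p-MAPKK", "MAPKKK*:p-MAPKK",
                        "pp-MAPKK", "kb3", "kd3", "k3")
    reactions += _cycle("MAPKK DP2", "M2KP", "pp-MAPKK", "M2KP:pp-MAPKK",
                        "p-MAPKK", "kb-3", "kd-3", "k-3")
    reactions += _cycle("MAPKK DP1", "M2KP", "p-MAPKK", "M2KP:p-MAPKK",
                        "MAPKK", "kb-2", "kd-2", "k-2")
    reactions += _cycle("MAPK P1", "pp-MAPKK", "MAPK", "pp-MAPKK:MAPK",
                        "p-MAPK", "kb4", "kd4", "k4")
    reactions += _cycle("MAPK P2", "pp-MAPKK", "p-MAPK", "pp-MAPKK:p-MAPK",
                        "pp-MAPK", "kb5", "kd5", "k5")
    reactions += _cycle("MAPK DP2", "MKP", "pp-MAPK", "MKP:pp-MAPK",
                        "p-MAPK", "kb-5", "kd-5", "k-5")
    reactions += _cycle("MAPK DP1", "MKP", "p-MAPK", "MKP:p-MAPK",
                        "MAPK", "kb-4", "kd-4", "k-4")

    n_r = len(reactions)
    N = np.zeros((len(SPECIES), n_r))
    idx_a = np.full(n_r, -1, dtype=np.int64)
    idx_b = np.full(n_r, -1, dtype=np.int64)
    k_index = np.full(n_r, -1, dtype=np.int64)
    stim = np.zeros(n_r, dtype=bool)
    name_to_slot = {n: i for i, n in enumerate(RATE_NAMES)}
    for j, r in enumerate(reactions):
        for sp, coeff in r.stoich.items():
            N[sp, j] = coeff
        idx_a[j] = r.rate_species[0]
        if len(r.rate_species) == 2:
            idx_b[j] = r.rate_species[1]
        if r.rate_constant != FIXED_ACTIVATION:
            k_index[j] = name_to_slot[r.rate_constant]
        stim[j] = r.stimulus_scaled

    return ReactionNetwork(
        topology=topology,
        species=SPECIES,
        reactions=tuple(reactions),
        stoichiometry=N,
        conservation=conservation_vectors(),
        _idx_a=idx_a,
        _idx_b=idx_b,
        _k_index=k_index,
        _stim_mask=stim,
    )


# ---------------------------------------------------------------------------
# Mass-action right-hand side and Jacobian

try:  # pragma: no cover - exercised indirectly everywhere
    from ._kernels import rhs_kernel as _rhs_kernel, jac_kernel as _jac_kernel
except ImportError:  # pragma: no cover
    _rhs_kernel = _jac_kernel = None


def _fluxes(network: ReactionNetwork, x: np.ndarray, keff: np.ndarray) -> np.ndarray:
    a = x[network._idx_a]
    b = np.where(network._idx_b >= 0, x[network._idx_b], 1.0)
    return keff * a * b


def rhs(network: ReactionNetwork, state, rates: KineticRates, S: float,
        *, check: bool = True) -> np.ndarray:
    """Time derivative of every species under mass action, dx/dt = N v(x).

    Each reaction contributes a flux k_i * prod of its rate species'
    concentrations; derivatives are the signed sums of these fluxes.
    """
    x = np.asarray(state, dtype=float)
    if check:
        if x.shape != (network.n_species,):
            raise InvalidStateError(f"state must have {network.n_species} entries")
        if np.any(x < 0):
            raise InvalidStateError("negative concentration in state")
        rates.validate_topology(network.topology)
    keff = network.effective_constants(rates, S)
    if _rhs_kernel is not None:
        return _rhs_kernel(x, keff, network._idx_a, network._idx_b,
                           network.stoichiometry)
    return network.stoichiometry @ _fluxes(network, x, keff)


def jacobian(network: ReactionNetwork, state, rates: KineticRates, S: float
             ) -> np.ndarray:
    """Analytic Jacobian d(rhs)/dx (n_species x n_species)."""
    x = np.asarray(state, dtype=float)
    keff = network.effective_constants(rates, S)
    if _jac_kernel is not None:
        return _jac_kernel(x, keff, network._idx_a, network._idx_b,
                           network.stoichiometry)
    n = network.n_species
    dv = np.zeros((network.n_reactions, n))
    for j in range(network.n_reactions):
        a, b = network._idx_a[j], network._idx_b[j]
        if b < 0:
            dv[j, a] = keff[j]
        else:
            dv[j, a] += keff[j] * x[b]
            dv[j, b] += keff[j] * x[a]
    return network.stoichiometry @ dv


def rhs_brute_force(network: ReactionNetwork, state, rates: KineticRates,
                    S: float) -> np.ndarray:
    """Reference evaluator: explicit loop over the reaction list.

    Independent of the vectorized path; used as a cross-check oracle.
    """
    x = np.asarray(state, dtype=float)
    kvec = {n: rates[n] for n in RATE_NAMES}
    kvec[FIXED_ACTIVATION] = 1.0
    dx = np.zeros_like(x)
    for r in network.reactions:
        k = kvec[r.rate_constant]
        if r.stimulus_scaled:
            k *= S
        flux = k
        for sp in r.rate_species:
            flux *= x[sp]
        for sp, coeff in r.stoich.items():
            dx[sp] += coeff * flux
    return dx
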