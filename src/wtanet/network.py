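"""Population structure and structured recurrent weights.

The circuit has N neurons, 80% pyramidal and 20% fast-spiking interneurons.
Two selective groups of pyramidal cells (A and B) each encode one of the two
choice alternatives; the remaining pyramidal cells are nonselective.
Connectivity is all-to-all (no self-connections).  Pyramidal-to-pyramidal
synapses carry a dimensionless weight: w_plus (> 1, "potentiated") within a
selective group, w_minus (< 1, "depressed") between the two selective groups
and from nonselective onto selective cells, and 1 elsewhere.  All synapses
to or from interneurons have weight 1.

w_minus is tied to w_plus through

    w_minus = 1 - f (w_plus - 1) / (1 - f),     f = group_size / N_E

so the mean recurrent excitatory drive in the spontaneous state,
f w_plus + (1 - f) w_minus = 1, is independent of w_plus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ConductanceRow, ConductanceTable, DEFAULT_CONDUCTANCES

__all__ = ["NetworkSpec", "compute_w_minus", "build_network", "conductances_for",
           "REFERENCE_SIZE",
           "GROUP_A", "GROUP_B", "GROUP_NONSELECTIVE", "GROUP_INHIBITORY"]

#: Network size for which the per-synapse recurrent conductance table is
#: quoted.  An all-to-all network of N neurons multiplies its recurrent
#: conductances by REFERENCE_SIZE / N so that the total recurrent input per
#: cell — the quantity mean-field theory holds fixed — is size-invariant.
REFERENCE_SIZE = 2000

GROUP_A = 0
GROUP_B = 1
GROUP_NONSELECTIVE = 2
GROUP_INHIBITORY = 3

GROUP_LABELS = {GROUP_A: "A", GROUP_B: "B",
                GROUP_NONSELECTIVE: "nonselective", GROUP_INHIBITORY: "inhibitory"}


def compute_w_minus(w_plus: float, f: float) -> float:
    """Depressed weight keeping f*w_plus + (1-f)*w_minus = 1.

    Raises for parameter combinations giving a nonpositive result.
    """
    if not 0.0 < f < 1.0:
        raise ValueError(f"selective fraction f must be in (0, 1), got {f}")
    if w_plus < 1.0:
        raise ValueError(f"w_plus must be >= 1, got {w_plus}")
    w_minus = 1.0 - f * (w_plus - 1.0) / (1.0 - f)
    if w_minus <= 0.0:
        raise ValueError(
            f"w_plus = {w_plus} with f = {f} gives w_minus = {w_minus:.4g} <= 0")
    return w_minus


@dataclass(frozen=True)
class NetworkSpec:
    """Sizes, membership labels, and weight values of one network instance."""

    N: int
    N_E: int
    N_I: int
    group_size: int
    w_plus: float
    w_minus: float
    membership: np.ndarray = field(repr=False)  # (N,) int codes, see GROUP_* constants

    @property
    def f(self) -> float:
        """Selective fraction group_size / N_E."""
        return self.group_size / self.N_E

    def members(self, group: int) -> np.ndarray:
        """Neuron indices belonging to one group code."""
        return np.nonzero(self.membership == group)[0]


def build_network(N: int = 480, group_size: int = 96,
                  w_plus: float = 1.9) -> tuple[NetworkSpec, np.ndarray]:
    """Construct the population structure and dense recurrent weight matrix.

    Membership is deterministic: excitatory indices [0, group_size) are
    group A, the next group_size are group B, the rest nonselective; the
    final N_I indices are interneurons.

    Returns ``(spec, W)`` where W has shape (N_E, N_E): entry (i, j) is the
    weight of the synapse from pyramidal cell j onto pyramidal cell i, with
    zero diagonal (no autapses).  Weights involving interneurons are
    implicitly 1 and are not stored.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    n_exc = 0.8 * N
    if abs(n_exc - round(n_exc)) > 1e-9:
        raise ValueError(f"N = {N} does not give an integer excitatory count (0.8 N)")
    n_exc = round(n_exc)
    n_inh = N - n_exc
    if 2 * group_size > n_exc:
        raise ValueError(f"two selective groups of {group_size} exceed N_E = {n_exc}")
    f = group_size / n_exc
    w_minus = compute_w_minus(w_plus, f)

    membership = np.full(N, GROUP_NONSELECTIVE, dtype=np.int64)
    membership[:group_size] = GROUP_A
    membership[group_size:2 * group_size] = GROUP_B
    membership[n_exc:] = GROUP_INHIBITORY

    exc_groups = membership[:n_exc]
    W = np.ones((n_exc, n_exc))
    sel_a = exc_groups == GROUP_A
    sel_b = exc_groups == GROUP_B
    nonsel = exc_groups == GROUP_NONSELECTIVE
    # within-group potentiation
    W[np.ix_(sel_a, sel_a)] = w_plus
    W[np.ix_(sel_b, sel_b)] = w_plus
    # depression: between selective groups and nonselective -> selective
    W[np.ix_(sel_a, sel_b)] = w_minus
    W[np.ix_(sel_b, sel_a)] = w_minus
    W[np.ix_(sel_a | sel_b, nonsel)] = w_minus
    np.fill_diagonal(W, 0.0)

    spec = NetworkSpec(N=N, N_E=n_exc, N_I=n_inh, group_size=group_size,
                       w_plus=w_plus, w_minus=w_minus, membership=membership)
    return spec, W


def conductances_for(cell_class: str, table: ConductanceTable | None = None) -> ConductanceRow:
    """Synaptic conductance row for one target cell class ('pyramidal' or 'interneuron')."""
    table = table if table is not None else DEFAULT_CONDUCTANCES
    return table.row(cell_class)


def full_weight_matrix(spec: NetworkSpec, W: np.ndarray) -> np.ndarray:
    """Expand the (N_E, N_E) pyramidal weight block to the (N, N_E) per-target form.

    Interneuron target rows are all 1, as used by the reference stepper.
    """
    out = np.ones((spec.N, spec.N_E))
    out[:spec.N_E] = W
    return out
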