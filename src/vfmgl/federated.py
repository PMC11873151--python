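"""Stage-2 federated orchestration: clients, server, weighted averaging.

Raw images never leave a center.  Each communication round the server
broadcasts the shared parameters (skipping every client's frozen
robustness-critical layers), clients run one local DDBL+KD training pass,
and the server aggregates the returned parameter arrays by a weighted
element-wise mean — weights proportional to each center's training-set
size by default.  The server keeps a message log of array names and shapes
only, making the privacy contract auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ArrayDataset
from .ddbl_kd import BatchHeterogeneityScore, Stage2Config, stage2_train

__all__ = ["ClientState", "SharedState", "aggregate", "run_round",
           "frozen_param_prefixes"]


def frozen_param_prefixes(model, frozen_layers) -> frozenset[str]:
    """Translate hookable layer names into dotted parameter prefixes."""
    prefixes: list[str] = []
    for layer in frozen_layers:
        prefixes.extend(model.layer_param_prefixes[layer])
    return frozenset(prefixes)


@dataclass
class ClientState:
    center_id: str
    model: object
    train_data: ArrayDataset
    frozen_layers: tuple[str, ...] = ()
    config: Stage2Config = field(default_factory=Stage2Config)
    last_scores: list[BatchHeterogeneityScore] | None = None

    @property
    def n_train(self) -> int:
        return len(self.train_data)

    @property
    def frozen_prefixes(self) -> frozenset[str]:
        return frozen_param_prefixes(self.model, self.frozen_layers)

    def parameters_message(self) -> dict[str, np.ndarray]:
        """What the client sends to the server: parameter arrays only."""
        return self.model.state_dict()


@dataclass
class SharedState:
    params: dict[str, np.ndarray]
    round_index: int = 0


def aggregate(params_list: list[dict[str, np.ndarray]],
              weights: np.ndarray | list[float]) -> SharedState:
    """Element-wise weighted mean of client parameter dicts.

    Weights are normalized to sum to one; the conventional choice is the
    per-center training-set size.
    """
    if not params_list:
        raise ValueError("need at least one client")
    w = np.asarray(weights, dtype=np.float64)
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    w = w / w.sum()
    keys = set(params_list[0])
    for p in params_list[1:]:
        if set(p) != keys:
            raise ValueError("clients expose different parameter sets")
    out: dict[str, np.ndarray] = {}
    for k in params_list[0]:
        shapes = {p[k].shape for p in params_list}
        if len(shapes) != 1:
            raise ValueError(f"shape mismatch for {k}: {shapes}")
        out[k] = sum(wi * p[k] for wi, p in zip(w, params_list))
    return SharedState(params=out)


def run_round(clients: list[ClientState], shared: SharedState,
              shared_model_factory, log: list[dict] | None = None
              ) -> tuple[list[ClientState], SharedState]:
    """One communication round: broadcast → local DDBL+KD pass → aggregate.

    ``shared_model_factory()`` builds a fresh model of the common
    architecture for server-side scoring on each client (the shared model's
    own prediction head is what DDBL compares against).  Client failures
    surface annotated with the center id.
    """
    shared_model = shared_model_factory()
    shared_model.load_state_dict(shared.params)
    shared_model.eval()
    for client in clients:
        # broadcast: shared params, but never overwrite frozen layers
        client.model.load_state_dict(shared.params,
                                     skip=client.frozen_prefixes)
        try:
            _, scores, _ = stage2_train(
                client.model, shared_model, client.train_data,
                client.frozen_prefixes, client.config, client.last_scores)
        except Exception as exc:
            raise RuntimeError(
                f"client {client.center_id} failed in round "
                f"{shared.round_index}: {exc}") from exc
        client.last_scores = scores
    messages = [c.parameters_message() for c in clients]
    if log is not None:
        for c, m in zip(clients, messages):
            log.append({"center_id": c.center_id, "n_train": c.n_train,
                        "round": shared.round_index,
                        "shapes": {k: v.shape for k, v in m.items()}})
    new_shared = aggregate(messages, [c.n_train for c in clients])
    new_shared.round_index = shared.round_index + 1
    return clients, new_shared
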