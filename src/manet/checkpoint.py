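"""Single-file network checkpoints with embedded architecture spec and seed.

A checkpoint stores the architecture description alongside every weight and
normalization buffer; the loader refuses a file whose spec hash differs from
an explicitly requested spec.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import CheckpointMismatchError
from .model import MANet, build_network
from .spec import NetworkSpec


def save_checkpoint(net: MANet, path, seed: int = 0) -> Path:
    path = Path(path)
    payload = {f"state/{k}": v for k, v in net.state_dict().items()}
    meta = json.dumps({"spec": net.spec.to_dict(), "seed": int(seed),
                       "spec_hash": net.spec.spec_hash()})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **payload)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path, expected_spec: NetworkSpec | None = None
                    ) -> tuple[MANet, NetworkSpec, int]:
    with np.load(Path(path)) as archive:
        meta = json.loads(archive["__meta__"].tobytes().decode())
        spec = NetworkSpec.from_dict(meta["spec"])
        if expected_spec is not None and expected_spec.spec_hash() != meta["spec_hash"]:
            raise CheckpointMismatchError(
                "checkpoint architecture hash does not match the requested spec "
                f"({meta['spec_hash'][:12]} != {expected_spec.spec_hash()[:12]})"
            )
        state = {k[len("state/"):]: archive[k] for k in archive.files
                 if k.startswith("state/")}
    net = build_network(spec, seed=meta["seed"])
    net.load_state_dict(state)
    return net, spec, int(meta["seed"])
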