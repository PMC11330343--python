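"""Trainable parameter bundle and checkpoint (de)serialization.

A checkpoint directory holds a single numpy array archive ``params.npz``
plus a JSON ``manifest.json`` recording shapes, the head count, and any
caller-supplied metadata (config echo, loss trajectory).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .fusion import ModalityProjections, ProjectionSet

PathLike = Union[str, Path]


@dataclass
class FusionParameters:
    """All trainable weights: per-modality input maps + fusion projections."""

    w_in_protein: np.ndarray  # H_protein_enc x H_fusion
    w_in_text: np.ndarray     # H_text_enc x H_fusion
    proj: ProjectionSet

    @property
    def h_fusion(self) -> int:
        return self.proj.h_fusion

    @classmethod
    def initialize(
        cls,
        h_protein: int,
        h_text: int,
        h_fusion: int = 64,
        n_heads: int = 8,
        seed: int = 0,
    ) -> "FusionParameters":
        rng = np.random.default_rng(seed)
        bound = np.sqrt(1.0 / h_fusion)
        return cls(
            w_in_protein=rng.uniform(-bound, bound, size=(h_protein, h_fusion)),
            w_in_text=rng.uniform(-bound, bound, size=(h_text, h_fusion)),
            proj=ProjectionSet.initialize(h_fusion, n_heads=n_heads, seed=seed + 1),
        )

    def as_flat_dict(self) -> dict[str, np.ndarray]:
        return {
            "w_in_protein": self.w_in_protein,
            "w_in_text": self.w_in_text,
            "protein.w_q": self.proj.protein.w_q,
            "protein.w_k": self.proj.protein.w_k,
            "protein.w_v": self.proj.protein.w_v,
            "protein.w_o": self.proj.protein.w_o,
            "text.w_q": self.proj.text.w_q,
            "text.w_k": self.proj.text.w_k,
            "text.w_v": self.proj.text.w_v,
            "text.w_o": self.proj.text.w_o,
        }

    @classmethod
    def from_flat_dict(
        cls, d: dict[str, np.ndarray], n_heads: int
    ) -> "FusionParameters":
        return cls(
            w_in_protein=d["w_in_protein"],
            w_in_text=d["w_in_text"],
            proj=ProjectionSet(
                protein=ModalityProjections(
                    d["protein.w_q"], d["protein.w_k"],
                    d["protein.w_v"], d["protein.w_o"],
                ),
                text=ModalityProjections(
                    d["text.w_q"], d["text.w_k"], d["text.w_v"], d["text.w_o"],
                ),
                n_heads=n_heads,
            ),
        )

    def copy(self) -> "FusionParameters":
        return FusionParameters.from_flat_dict(
            {k: v.copy() for k, v in self.as_flat_dict().items()},
            n_heads=self.proj.n_heads,
        )

    def save(self, directory: PathLike, metadata: Optional[dict] = None) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        flat = self.as_flat_dict()
        np.savez(directory / "params.npz", **{k.replace(".", "__"): v
                                              for k, v in flat.items()})
        manifest = {
            "n_heads": self.proj.n_heads,
            "h_fusion": self.h_fusion,
            "shapes": {k: list(v.shape) for k, v in flat.items()},
            "metadata": metadata or {},
        }
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, directory: PathLike) -> tuple["FusionParameters", dict]:
        directory = Path(directory)
        with open(directory / "manifest.json") as fh:
            manifest = json.load(fh)
        with np.load(directory / "params.npz") as npz:
            flat = {k.replace("__", "."): npz[k] for k in npz.files}
        return cls.from_flat_dict(flat, n_heads=manifest["n_heads"]), manifest


__all__ = ["FusionParameters"]
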