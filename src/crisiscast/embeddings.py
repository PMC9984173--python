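"""Word-embedding table in word2vec text format.

The table maps each vocabulary word to a fixed-dimension real vector.
Looking up an absent word raises :class:`KeyError` — out-of-vocabulary
handling is an explicit policy of the caller, never a silent zero vector.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


class EmbeddingTable:
    """Immutable word -> vector mapping with uniform dimension."""

    def __init__(self, vectors: dict[str, np.ndarray]):
        if not vectors:
            raise ValueError("embedding table cannot be empty")
        dims = {np.asarray(v).shape for v in vectors.values()}
        if len(dims) != 1 or len(next(iter(dims))) != 1:
            raise ValueError(f"all vectors must share one dimension, got shapes {dims}")
        self._words = list(vectors)
        self._index = {w: i for i, w in enumerate(self._words)}
        self._matrix = np.asarray([vectors[w] for w in self._words], dtype=float)

    @property
    def dim(self) -> int:
        return self._matrix.shape[1]

    @property
    def words(self) -> list[str]:
        return list(self._words)

    def __len__(self) -> int:
        return len(self._words)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def vector(self, word: str) -> np.ndarray:
        """Return the vector for ``word``; KeyError if absent."""
        return self._matrix[self._index[word]]

    def __getitem__(self, word: str) -> np.ndarray:
        return self.vector(word)

    def matrix_for(self, words: list[str]) -> np.ndarray:
        """Stack vectors for ``words`` (KeyError on any absent word)."""
        return self._matrix[[self._index[w] for w in words]]

    # -- word2vec text serialization ("V D" header, then word + D floats) --

    def save_word2vec(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self)} {self.dim}\n")
            for w in self._words:
                vec = " ".join(format(x, ".8g") for x in self._matrix[self._index[w]])
                fh.write(f"{w} {vec}\n")

    @classmethod
    def load_word2vec(cls, path: str | Path) -> "EmbeddingTable":
        with open(path) as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise ValueError("malformed word2vec header, expected 'V D'")
            n, dim = int(header[0]), int(header[1])
            vectors: dict[str, np.ndarray] = {}
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                if len(parts) != dim + 1:
                    raise ValueError(f"bad vector line for {parts[0]!r}")
                vectors[parts[0]] = np.asarray([float(x) for x in parts[1:]])
        if len(vectors) != n:
            raise ValueError(f"header declared {n} words, found {len(vectors)}")
        return cls(vectors)
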