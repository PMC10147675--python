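"""Token vocabulary shared by the dual encoder and the seq2seq model."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

PAD, BOS, EOS, UNK = "[PAD]", "[BOS]", "[EOS]", "[UNK]"
SPECIALS = (PAD, BOS, EOS, UNK)


@dataclass(frozen=True)
class Vocabulary:
    tokens: tuple[str, ...]
    index: dict[str, int]

    @classmethod
    def build(cls, sequences: Iterable[Sequence[str]]) -> "Vocabulary":
        seen: dict[str, None] = {}
        for seq in sequences:
            for tok in seq:
                seen.setdefault(tok, None)
        tokens = SPECIALS + tuple(sorted(seen))
        return cls(tokens=tokens, index={t: i for i, t in enumerate(tokens)})

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return self.index[PAD]

    @property
    def bos_id(self) -> int:
        return self.index[BOS]

    @property
    def eos_id(self) -> int:
        return self.index[EOS]

    def encode(self, tokens: Sequence[str], strict: bool = False) -> list[int]:
        if strict:
            missing = [t for t in tokens if t not in self.index]
            if missing:
                raise KeyError(f"tokens missing from vocabulary: {missing}")
        unk = self.index[UNK]
        return [self.index.get(t, unk) for t in tokens]

    def decode(self, ids: Sequence[int]) -> list[str]:
        return [self.tokens[i] for i in ids]
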