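"""Gene-pair signatures: oriented pair lists plus the vote-threshold rule.

Orientation convention throughout: within a pair ``(gene_a, gene_b)``,
gene_a has the higher expression in histological-grade-1 (HG1) tumors.
A sample in which gene_a < gene_b therefore casts one vote for HG3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["Signature"]

_HEADER_COMMENT = (
    "# oriented gene pairs: gene_a has the higher expression in HG1 samples"
)


@dataclass(frozen=True)
class Signature:
    """An ordered list of oriented gene pairs with the majority-vote rule.

    ``pairs[i] = (gene_a, gene_b)`` with gene_a higher in HG1. A sample
    is called HG3 when at least half (``ceil(k/2)`` of k evaluable
    pairs) of its pair votes are for HG3.
    """

    pairs: tuple[tuple[str, str], ...]
    symbols: dict[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.pairs) < 1:
            raise ValueError("a signature needs at least one gene pair")
        seen: set[frozenset[str]] = set()
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"degenerate pair ({a}, {b})")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate unordered pair ({a}, {b})")
            seen.add(key)
        object.__setattr__(self, "pairs", tuple((str(a), str(b)) for a, b in self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def genes(self) -> set[str]:
        return {g for pair in self.pairs for g in pair}

    def symbol(self, gene_id: str) -> str:
        return self.symbols.get(gene_id, gene_id)

    @classmethod
    def from_pairs(
        cls, pairs, symbols: dict[str, str] | None = None
    ) -> "Signature":
        return cls(tuple((str(a), str(b)) for a, b in pairs), dict(symbols or {}))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Signature":
        """Read a four-column signature table.

        Columns: geneA_id, geneA_symbol, geneB_id, geneB_symbol; one
        leading ``#`` comment line states the orientation convention.
        """
        pairs: list[tuple[str, str]] = []
        symbols: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if fields[0] == "geneA_id":  # optional column-name row
                    continue
                if len(fields) < 4:
                    raise ValueError(f"signature row has fewer than 4 columns: {line!r}")
                a_id, a_sym, b_id, b_sym = fields[:4]
                pairs.append((a_id, b_id))
                symbols[a_id] = a_sym
                symbols[b_id] = b_sym
        if not pairs:
            raise ValueError(f"no gene pairs found in {path}")
        return cls.from_pairs(pairs, symbols)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(_HEADER_COMMENT + "\n")
            fh.write("geneA_id\tgeneA_symbol\tgeneB_id\tgeneB_symbol\n")
            for a, b in self.pairs:
                fh.write(f"{a}\t{self.symbol(a)}\t{b}\t{self.symbol(b)}\n")
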