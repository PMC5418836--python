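"""Gene panel: the Mendelian Parkinson's disease genes plus GBA.

The analysis is restricted to a curated panel of genes with an established
role in PD.  Each gene carries an inheritance ``mode``:

* ``dominant`` — a single well-established pathogenic allele is a primary
  cause (e.g. LRRK2, SNCA point mutations, VPS35).
* ``recessive`` — a primary cause requires biallelic pathogenic alleles
  (homozygous, compound heterozygous, or SNV plus a CNV loss allele),
  e.g. PARK2/PRKN, PINK1, ATP13A2.
* ``risk`` — heterozygous variants increase risk without being a Mendelian
  cause.  GBA is always carried with this mode and is tabulated separately
  from the Mendelian genes throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

MODES = ("dominant", "recessive", "risk")

GBA = "GBA"


@dataclass(frozen=True)
class GeneDefinition:
    """One panel gene and its inheritance mode."""

    symbol: str
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown inheritance mode {self.mode!r} for {self.symbol}")


class GenePanel:
    """Ordered collection of :class:`GeneDefinition` with lookup helpers."""

    def __init__(self, genes: list[GeneDefinition] | dict[str, str]):
        if isinstance(genes, dict):
            genes = [GeneDefinition(sym, mode) for sym, mode in genes.items()]
        self._genes: dict[str, GeneDefinition] = {}
        for g in genes:
            if g.symbol in self._genes:
                raise ValueError(f"duplicate gene {g.symbol} in panel")
            self._genes[g.symbol] = g
        if GBA in self._genes and self._genes[GBA].mode != "risk":
            raise ValueError("GBA must have mode 'risk'")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._genes

    def __iter__(self):
        return iter(self._genes.values())

    def __len__(self) -> int:
        return len(self._genes)

    def mode(self, symbol: str) -> str:
        return self._genes[symbol].mode

    @property
    def symbols(self) -> list[str]:
        return list(self._genes)

    @property
    def mendelian_genes(self) -> list[str]:
        return [g.symbol for g in self if g.mode in ("dominant", "recessive")]

    @property
    def dominant_genes(self) -> list[str]:
        return [g.symbol for g in self if g.mode == "dominant"]

    @property
    def recessive_genes(self) -> list[str]:
        return [g.symbol for g in self if g.mode == "recessive"]

    def to_dict(self) -> dict[str, str]:
        return {g.symbol: g.mode for g in self}


def default_panel() -> GenePanel:
    """Ten Mendelian PD genes plus the GBA risk gene."""
    return GenePanel(
        {
            "SNCA": "dominant",
            "LRRK2": "dominant",
            "VPS35": "dominant",
            "EIF4G1": "dominant",
            "PARK2": "recessive",
            "PINK1": "recessive",
            "PARK7": "recessive",
            "ATP13A2": "recessive",
            "FBXO7": "recessive",
            "PLA2G6": "recessive",
            GBA: "risk",
        }
    )
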