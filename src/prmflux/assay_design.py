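"""In-silico tryptic assay design for targeted proteomics.

Generates candidate peptides for proteins of interest by tryptic digestion,
applies the selection rules used for PRM assay construction (length window,
methionine exclusion), and hosts the packaged target registries: the 41
autophagy-relevant proteins originally shortlisted and the final 37-protein
panel for which quantifiable peptides were obtained.

Coordinates are 1-based and inclusive throughout, i.e. ``ATG3[12-24]`` denotes
residues 12..24 of the ATG3 sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "CANONICAL_RESIDUES",
    "ProteinTarget",
    "CandidatePeptide",
    "digest",
    "filter_candidates",
    "load_registry",
    "PACKAGED_REGISTRIES",
]

#: The 20 canonical amino acids, one-letter codes.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Names of registries shipped with the package.
PACKAGED_REGISTRIES = ("table1_41", "final_37")


@dataclass(frozen=True)
class ProteinTarget:
    """A monitored protein of interest.

    ``sequence`` may be ``None`` for registry-only entries (the packaged
    registries carry accession/gene/category but no sequence).
    """

    accession: str
    gene: str = ""
    category: str = ""
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if self.sequence is not None:
            bad = _first_non_canonical(self.sequence)
            if bad is not None:
                pos, res = bad
                raise ValueError(
                    f"non-canonical residue {res!r} at position {pos} "
                    f"in sequence of {self.accession}"
                )


@dataclass
class CandidatePeptide:
    """A tryptic peptide candidate with 1-based inclusive coordinates."""

    parent: str
    sequence: str
    start: int
    end: int
    missed_cleavages: int = 0
    verdict: str | None = None

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"coordinates [{self.start}-{self.end}] inconsistent with "
                f"length {len(self.sequence)} of {self.sequence!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:  # e.g. "ATG3[12-24]: ALEVAEYLTPVLK"
        return f"{self.parent}[{self.start}-{self.end}]: {self.sequence}"


def _first_non_canonical(sequence: str) -> tuple[int, str] | None:
    for i, res in enumerate(sequence, start=1):
        if res not in CANONICAL_RESIDUES:
            return i, res
    return None


def digest(
    sequence: str,
    missed_cleavages: int = 0,
    *,
    parent: str = "",
    proline_rule: bool = True,
) -> list[CandidatePeptide]:
    """Fully tryptic digestion of ``sequence``.

    Cleaves C-terminal to K or R; with ``proline_rule`` (the standard Keil
    rule, on by default) no cleavage occurs when the following residue is
    proline. Returns peptides with 0..``missed_cleavages`` internal missed
    cleavage sites, ordered by start position then length. At 0 missed
    cleavages the peptides tile the sequence without gaps.

    Raises
    ------
    ValueError
        If the sequence is empty, contains a non-canonical residue (the
        message names the residue and its 1-based position), or
        ``missed_cleavages`` is negative.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be non-negative")
    bad = _first_non_canonical(sequence)
    if bad is not None:
        pos, res = bad
        raise ValueError(f"non-canonical residue {res!r} at position {pos}")

    # Cleavage boundaries: 0-based index *after* which the chain is cut.
    cuts = [0]
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and not (proline_rule and sequence[i + 1] == "P"):
            cuts.append(i + 1)
    cuts.append(len(sequence))

    peptides: list[CandidatePeptide] = []
    for i in range(len(cuts) - 1):
        for mc in range(missed_cleavages + 1):
            j = i + 1 + mc
            if j >= len(cuts):
                break
            start, end = cuts[i], cuts[j]
            peptides.append(
                CandidatePeptide(
                    parent=parent,
                    sequence=sequence[start:end],
                    start=start + 1,
                    end=end,
                    missed_cleavages=mc,
                )
            )
    return peptides


def filter_candidates(
    peptides: Iterable[CandidatePeptide],
    *,
    min_length: int = 7,
    max_length: int = 25,
    excluded_residues: str = "M",
    allow_list: Iterable[str] | None = None,
) -> list[CandidatePeptide]:
    """Assign selection verdicts to candidate peptides.

    A peptide passes iff its length lies in ``[min_length, max_length]`` and
    it contains none of ``excluded_residues`` (methionine by default, which is
    prone to post-lysis oxidation). When several rules fail, the verdict
    reports the first failure in the order length -> excluded residue, so
    diagnostics are deterministic. Nothing is dropped: every input peptide is
    returned (as a copy) with a verdict.

    ``allow_list`` is an optional detectability hook: when given, a peptide
    whose sequence is absent from the list is demoted to
    ``"fail_detectability"`` even if the intrinsic rules pass. It stands in
    for screening against prior MS evidence, which is out of scope here.
    """
    allowed = set(allow_list) if allow_list is not None else None
    out: list[CandidatePeptide] = []
    for pep in peptides:
        if not (min_length <= pep.length <= max_length):
            verdict = "fail_length"
        elif any(res in pep.sequence for res in excluded_residues):
            verdict = "fail_methionine"
        elif allowed is not None and pep.sequence not in allowed:
            verdict = "fail_detectability"
        else:
            verdict = "pass"
        out.append(replace(pep, verdict=verdict))
    return out


def _registry_path(table: str | Path):
    if isinstance(table, str) and table in PACKAGED_REGISTRIES:
        return resources.files("prmflux.data").joinpath(f"{table}.tsv")
    return Path(table)


def load_registry(table: str | Path) -> list[ProteinTarget]:
    """Load a target registry from a packaged name or a TSV path.

    Packaged registries: ``"table1_41"`` (the 41 shortlisted proteins of
    interest) and ``"final_37"`` (the final panel with quantifiable
    peptides). A registry file is tab-separated with header
    ``accession<TAB>gene<TAB>category``.

    Raises ``ValueError`` on an empty file, a malformed row (message carries
    the line number) or a duplicate accession.
    """
    path = _registry_path(table)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty registry: {table}")
    header = [h.strip().lower() for h in lines[0].split("\t")]
    if header[:3] != ["accession", "gene", "category"]:
        raise ValueError(f"bad registry header in {table}: {lines[0]!r}")
    targets: list[ProteinTarget] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) < 3 or not fields[0].strip():
            raise ValueError(f"malformed registry row at line {lineno}: {line!r}")
        acc, gene, category = (f.strip() for f in fields[:3])
        if acc in seen:
            raise ValueError(f"duplicate accession {acc} at line {lineno}")
        seen.add(acc)
        targets.append(ProteinTarget(accession=acc, gene=gene, category=category))
    return targets
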