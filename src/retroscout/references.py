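"""Bundled reference domain alignments and lineage material.

The package ships small synthetic reference alignments for the six
retrotransposon domain classes (``data/domains/*.synthetic.faa``), standing in
for conserved-domain profiles, with one variant pair per retroelement lineage
(Tf-like and Ty3-like; the chromodomain is a Ty3-lineage feature). The same
sequences seed the synthetic-genome generator and the lineage-assignment
references, so planted elements and the scanner's models are mutually
consistent. The scanner itself is model-pluggable: externally derived profiles
can be substituted.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .domains import DOMAIN_NAMES, DomainModel, build_model, calibrate_threshold

LINEAGES = ("tf_like", "ty3_like")

#: domain cassette order encoded by each lineage's internal ORF
CASSETTE_ORDER = {
    "tf_like": ("gag", "protease", "reverse_transcriptase", "rnase_h", "integrase"),
    "ty3_like": (
        "gag",
        "protease",
        "reverse_transcriptase",
        "rnase_h",
        "integrase",
        "chromodomain",
    ),
}

#: domains used for family clustering and lineage placement
TRIPLET_DOMAINS = ("reverse_transcriptase", "rnase_h", "integrase")

_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(standard_dna_table.forward_table.items()):
    _AA_TO_CODONS.setdefault(aa, []).append(codon)


@lru_cache(maxsize=None)
def load_domain_alignments() -> dict[str, list[tuple[str, str, str]]]:
    """name -> list of (sequence id, lineage, protein sequence)."""
    out: dict[str, list[tuple[str, str, str]]] = {}
    base = resources.files("retroscout").joinpath("data/domains")
    for name in DOMAIN_NAMES:
        rows: list[tuple[str, str, str]] = []
        text = base.joinpath(f"{name}.synthetic.faa").read_text()
        rid = lineage = None
        seq_parts: list[str] = []
        for line in text.splitlines():
            if line.startswith(">"):
                if rid is not None:
                    rows.append((rid, lineage, "".join(seq_parts)))
                header = line[1:].split()
                rid = header[0]
                lineage = dict(
                    kv.split("=") for kv in header[1:] if "=" in kv
                ).get("lineage", "")
                seq_parts = []
            elif line.strip():
                seq_parts.append(line.strip())
        if rid is not None:
            rows.append((rid, lineage, "".join(seq_parts)))
        out[name] = rows
    return out


def domain_length(name: str) -> int:
    return len(load_domain_alignments()[name][0][2])


def translated_background(gc: float = 0.40) -> np.ndarray:
    """Amino-acid frequencies of translating random DNA of the given GC
    content (stops excluded, renormalized). Using this as the log-odds and
    null-calibration background matches what the scanner actually scores:
    translated windows of an AT-rich genome, not uniform residue soup."""
    from .domains import AA_ALPHABET

    p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "C": gc / 2, "G": gc / 2}
    freqs = dict.fromkeys(AA_ALPHABET, 0.0)
    for codon, aa in standard_dna_table.forward_table.items():
        freqs[aa] += p[codon[0]] * p[codon[1]] * p[codon[2]]
    total = sum(freqs.values())
    return np.array([freqs[a] / total for a in AA_ALPHABET])


def build_domain_models(
    alpha: float = 1e-3, null_draws: int = 1000, seed: int = 0, gc: float = 0.40
) -> list[DomainModel]:
    """Build and calibrate one PSSM per bundled domain class."""
    background = translated_background(gc)
    models = []
    for name, rows in load_domain_alignments().items():
        model = build_model([seq for _, _, seq in rows], name=name,
                            background=background)
        model.threshold = calibrate_threshold(
            model, null_draws=null_draws, alpha=alpha, seed=seed,
            background=background,
        )
        models.append(model)
    return models


def lineage_proteins(lineage: str) -> dict[str, str]:
    """Ancestral protein per domain for one lineage (the ``.1`` variant)."""
    out = {}
    for name in CASSETTE_ORDER[lineage]:
        for rid, lin, seq in load_domain_alignments()[name]:
            if lin == lineage and rid.endswith(".1"):
                out[name] = seq
                break
    return out


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Back-translate with a uniform choice among synonymous codons."""
    codons = []
    for aa in protein:
        options = _AA_TO_CODONS[aa]
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


#: 12-mer carrying a stop codon in all three frames of both strands
#: (TAA at offsets 1/5/9 forward; TAG at 1/5/9 of the reverse complement)
STOP_ISLAND = "CTAACTAACTAA"


def sprinkle_stop_islands(seq: str, spacing: int = 90, offset: int = 30) -> str:
    """Overwrite periodic stop islands so no frame of either strand has a
    long open reading frame: non-coding sequence (LTRs, spacers) should not
    be able to masquerade as a protein domain."""
    s = list(seq)
    pos = offset
    last = -1
    while pos + len(STOP_ISLAND) <= len(s):
        s[pos : pos + len(STOP_ISLAND)] = STOP_ISLAND
        last = pos
        pos += spacing
    # keep the tail covered too (windows straddling the sequence edge)
    tail = len(s) - 24
    if tail >= 0 and tail - last > 40:
        s[tail : tail + len(STOP_ISLAND)] = STOP_ISLAND
    return "".join(s)


def lineage_ltr(lineage: str, length: int) -> str:
    """Ancestral LTR for a lineage: deterministic, TG...CA-terminated,
    ORF-free in all six frames."""
    seed = 9100 + LINEAGES.index(lineage)
    rng = np.random.default_rng(seed)
    body = "".join(rng.choice(list("ACGT"), size=length, p=[0.3, 0.2, 0.2, 0.3]))
    return sprinkle_stop_islands("TG" + body[2:-2] + "CA")


@lru_cache(maxsize=None)
def reference_triplets() -> list[tuple[str, str, dict[str, str]]]:
    """Reference (name, lineage, domain -> nucleotide sequence) records for
    lineage assignment, back-translated deterministically."""
    refs = []
    alignments = load_domain_alignments()
    ids = []
    for rid, lin, _ in alignments["reverse_transcriptase"]:
        ids.append((rid.split("|")[-1], lin))
    for k, (rid, lin) in enumerate(ids):
        rng = np.random.default_rng(5200 + k)
        triplet = {}
        for dom in TRIPLET_DOMAINS:
            for rid2, lin2, seq in alignments[dom]:
                if rid2.split("|")[-1] == rid:
                    triplet[dom] = back_translate(seq, rng)
        refs.append((f"ref_{rid}", lin, triplet))
    return refs
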