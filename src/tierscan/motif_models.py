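"""Position-specific probability models of DNA motifs.

A :class:`MotifModel` is a width-W matrix of per-position nucleotide
probabilities (alphabet order A,C,G,T) together with a zero-order
background, from which base-2 log-odds scores, an IUPAC consensus and an
informative-position mask are derived.  Models can be built from an IUPAC
consensus string (:func:`consensus_to_pssm`) or from a collection of
aligned sites (:func:`build_pssm_from_sites`), and round-trip through the
MEME minimal motif format and a JSON dump.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .alphabet import (
    ALPHABET,
    BASE_INDEX,
    IUPAC,
    UNIFORM_BACKGROUND,
    normalize_background,
    validate_acgt,
    validate_iupac,
)

#: The canonical full-site dihexamer: two hexamers around a free 3-bp spacer.
FULL_SITE_CONSENSUS = "AGAACANNNTGTTCT"

#: The canonical half-site hexamer (forward orientation).
HALF_SITE_CONSENSUS = "AGAACA"

#: Default match probabilities for the strict and mismatch-tolerant models.
IDEAL_MATCH_PROB = 0.997
LENIENT_MATCH_PROB = 0.85

# inverse IUPAC lookup: frozenset of bases -> degenerate code
_BASES_TO_IUPAC = {frozenset(v): k for k, v in IUPAC.items()}


@dataclass
class MotifModel:
    """A probability matrix over A,C,G,T with background and log-odds views."""

    name: str
    probs: np.ndarray            # (W, 4) row-stochastic
    background: np.ndarray       # (4,) zero-order frequencies
    informative_mask: np.ndarray = field(default=None)  # (W,) bool

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be a (W, 4) matrix")
        if np.any(self.probs < 0):
            raise ValueError("probs must be non-negative")
        rowsums = self.probs.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-4):
            raise ValueError("each probs row must sum to 1")
        # renormalize only sloppy rows so exact inputs round-trip bit-for-bit
        off = np.abs(rowsums - 1.0) > 1e-9
        if np.any(off):
            self.probs = self.probs.copy()
            self.probs[off] /= rowsums[off, None]
        self.background = normalize_background(self.background)
        if self.informative_mask is None:
            # a position is informative unless it simply copies the background
            self.informative_mask = np.any(
                np.abs(self.probs - self.background[None, :]) > 1e-9, axis=1
            )
        else:
            self.informative_mask = np.asarray(self.informative_mask, dtype=bool)
            if self.informative_mask.shape != (self.width,):
                raise ValueError("informative_mask length must equal model width")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """Base-2 log of probs/background, shape (W, 4).

        Undefined (raises) when any probability is exactly zero; rebuild
        the model with a pseudocount to score such motifs.
        """
        if np.any(self.probs == 0):
            raise ValueError(
                f"model {self.name!r}: log-odds undefined with zero "
                "probabilities; apply a pseudocount"
            )
        return np.log2(self.probs / self.background[None, :])

    @property
    def consensus(self) -> str:
        """IUPAC consensus: code for the max-probability letter set per row."""
        return consensus_string(self.probs)

    def is_palindromic(self, tol: float = 1e-9) -> bool:
        """True when the model equals its own reverse complement."""
        return bool(
            np.allclose(self.probs, reverse_complement_model(self).probs, atol=tol)
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "width": self.width,
            "alphabet": ALPHABET,
            "probs": self.probs.tolist(),
            "background": self.background.tolist(),
            "log_odds": self.log_odds.tolist(),
            "consensus": self.consensus,
            "informative_mask": self.informative_mask.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "MotifModel":
        return cls(
            name=d["name"],
            probs=np.asarray(d["probs"], dtype=float),
            background=np.asarray(d["background"], dtype=float),
            informative_mask=np.asarray(d["informative_mask"], dtype=bool),
        )


@dataclass
class SiteCollection:
    """A set of equal-length unambiguous nucleotide strings."""

    sites: list
    width: int = 0

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("site collection is empty")
        self.sites = [validate_acgt(s, context="site") for s in self.sites]
        widths = {len(s) for s in self.sites}
        if len(widths) != 1:
            raise ValueError(f"sites have unequal lengths: {sorted(widths)}")
        self.width = widths.pop()

    def __len__(self) -> int:
        return len(self.sites)

    def counts(self) -> np.ndarray:
        """Per-position base counts, shape (W, 4)."""
        counts = np.zeros((self.width, 4), dtype=float)
        for s in self.sites:
            for i, ch in enumerate(s):
                counts[i, BASE_INDEX[ch]] += 1
        return counts


def consensus_string(probs: np.ndarray, degeneracy_threshold: float = 0.5) -> str:
    """Derive an IUPAC consensus from a probability matrix.

    Rows whose maximum probability falls below *degeneracy_threshold* become
    ``N``.  Letters within 1e-9 of the row maximum are pooled into the
    matching degenerate code.
    """
    out = []
    for row in np.asarray(probs, dtype=float):
        mx = row.max()
        if mx < degeneracy_threshold:
            out.append("N")
            continue
        letters = frozenset(ALPHABET[b] for b in range(4) if row[b] >= mx - 1e-9)
        out.append(_BASES_TO_IUPAC[letters])
    return "".join(out)


def consensus_to_pssm(
    consensus: str,
    match_prob: float = LENIENT_MATCH_PROB,
    background: Sequence[float] = UNIFORM_BACKGROUND,
    name: str | None = None,
) -> MotifModel:
    """Build a probability model from an IUPAC consensus string.

    Single-letter positions give *match_prob* to that letter and share the
    remainder equally among the other three.  Multi-letter codes split
    *match_prob* equally among the allowed letters.  ``N`` positions copy
    the background row and are marked non-informative.
    """
    if not consensus:
        raise ValueError("consensus must be non-empty")
    cons = validate_iupac(consensus)
    if not match_prob > 0.25:
        raise ValueError(
            f"match_prob {match_prob} <= 0.25 would make the model uninformative"
        )
    if match_prob > 1:
        raise ValueError("match_prob must be <= 1")
    bg = normalize_background(background)
    width = len(cons)
    probs = np.empty((width, 4))
    mask = np.ones(width, dtype=bool)
    for i, code in enumerate(cons):
        allowed = IUPAC[code]
        if code == "N":
            probs[i] = bg
            mask[i] = False
        else:
            rest = (1.0 - match_prob) / (4 - len(allowed))
            probs[i] = rest
            for b in allowed:
                probs[i, BASE_INDEX[b]] = match_prob / len(allowed)
    return MotifModel(
        name=name or cons, probs=probs, background=bg, informative_mask=mask
    )


def build_pssm_from_sites(
    sites: SiteCollection | Iterable[str],
    pseudocount: float = 1.0,
    background: Sequence[float] = UNIFORM_BACKGROUND,
    name: str = "sites",
) -> MotifModel:
    """Estimate a probability model from aligned sites.

    ``probs[i][b] = (count[i][b] + pseudocount * background[b]) / (n + pseudocount)``

    With a pseudocount of 0 unobserved letters get probability zero; such a
    model reports counts/consensus fine but cannot be scored (log-odds are
    rejected as undefined until a pseudocount is applied).
    """
    if not isinstance(sites, SiteCollection):
        sites = SiteCollection(list(sites))
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    bg = normalize_background(background)
    counts = sites.counts()
    n = len(sites)
    probs = (counts + pseudocount * bg[None, :]) / (n + pseudocount)
    return MotifModel(name=name, probs=probs, background=bg)


def reverse_complement_model(model: MotifModel) -> MotifModel:
    """Reverse the rows and swap A<->T, C<->G within each row."""
    # column permutation for A,C,G,T -> T,G,C,A
    perm = [3, 2, 1, 0]
    return MotifModel(
        name=model.name + "_rc",
        probs=model.probs[::-1, perm].copy(),
        background=model.background[perm].copy(),
        informative_mask=model.informative_mask[::-1].copy(),
    )


def information_content(model: MotifModel) -> tuple[np.ndarray, float]:
    """Per-position information content in bits (uniform-background convention).

    ``IC_i = 2 + sum_b p_ib * log2(p_ib)``; returns (per-position array, total).
    """
    p = model.probs
    plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    per_pos = 2.0 + plogp.sum(axis=1)
    return per_pos, float(per_pos.sum())


def ideal_full_site_model(
    background: Sequence[float] = UNIFORM_BACKGROUND,
) -> MotifModel:
    """The strict full-site dihexamer model (near-one match probability)."""
    return consensus_to_pssm(
        FULL_SITE_CONSENSUS, IDEAL_MATCH_PROB, background, name="full_site_ideal"
    )


def lenient_full_site_model(
    background: Sequence[float] = UNIFORM_BACKGROUND,
) -> MotifModel:
    """The mismatch-tolerant full-site model."""
    return consensus_to_pssm(
        FULL_SITE_CONSENSUS, LENIENT_MATCH_PROB, background, name="full_site_lenient"
    )


def half_site_model(
    background: Sequence[float] = UNIFORM_BACKGROUND,
    match_prob: float = IDEAL_MATCH_PROB,
) -> MotifModel:
    """The isolated hexamer model (forward orientation)."""
    return consensus_to_pssm(
        HALF_SITE_CONSENSUS, match_prob, background, name="half_site"
    )


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def write_meme(models: Iterable[MotifModel], path) -> None:
    """Write models in MEME minimal format (version 4)."""
    models = list(models)
    if not models:
        raise ValueError("no models to write")
    bg = models[0].background
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write("ALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            "A {:.8f} C {:.8f} G {:.8f} T {:.8f}\n\n".format(*bg)
        )
        for m in models:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in m.probs:
                fh.write(" {:.8f} {:.8f} {:.8f} {:.8f}\n".format(*row))
            fh.write("\n")


def read_meme(path) -> list[MotifModel]:
    """Read a MEME minimal motif file; returns one model per MOTIF block."""
    models: list[MotifModel] = []
    background = UNIFORM_BACKGROUND.copy()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    if not any(ln.startswith("MEME version") for ln in lines[:5]):
        raise ValueError(f"{path}: missing 'MEME version' header")
    while i < len(lines):
        ln = lines[i].strip()
        if ln.startswith("Background letter frequencies"):
            toks = lines[i + 1].split()
            freq = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
            background = np.array([freq[b] for b in ALPHABET])
            i += 2
            continue
        if ln.startswith("MOTIF"):
            name = ln.split()[1] if len(ln.split()) > 1 else f"motif_{len(models)}"
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                i += 1
            if i >= len(lines):
                raise ValueError(f"{path}: MOTIF {name} has no probability matrix")
            header = lines[i].strip()
            w = None
            toks = header.split()
            for j, t in enumerate(toks):
                if t == "w=":
                    w = int(toks[j + 1])
            i += 1
            rows = []
            while i < len(lines):
                parts = lines[i].split()
                if len(parts) == 4:
                    try:
                        rows.append([float(x) for x in parts])
                    except ValueError:
                        break
                    i += 1
                else:
                    break
            if w is not None and len(rows) != w:
                raise ValueError(
                    f"{path}: MOTIF {name} declares w={w} but has {len(rows)} rows"
                )
            probs = np.asarray(rows)
            # clip exact zeros so log-odds stay finite
            probs = np.clip(probs, 1e-9, None)
            models.append(MotifModel(name=name, probs=probs, background=background))
            continue
        i += 1
    if not models:
        raise ValueError(f"{path}: no MOTIF blocks found")
    return models
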