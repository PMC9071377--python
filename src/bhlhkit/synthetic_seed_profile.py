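"""Synthetic seed alignment for the bHLH domain profile.

This is a constructed (synthetic) stand-in reference alignment, not a
transcription of any curated HLH profile: eight gap-aligned domain
sequences built around a single consensus with the canonical bHLH
architecture — a basic DNA-contacting region, two amphipathic helices
and the connecting loop.  The rule-relevant residues of the basic region
(the H/K-1, E-2, R-4 and R-5 positions used for E-box/G-box binding
classification) are placed at fixed, documented columns.  The default
simulator plants domains drawn from this same consensus, which makes the
profile/planted-domain pair internally consistent and fully testable.
"""

from __future__ import annotations

# Region layout (profile columns, 0-based half-open):
#   basic   [0, 13)   — DNA-contacting basic region
#   helix1  [13, 28)
#   loop    [28, 36)
#   helix2  [36, 51)
REGION_SPEC: dict[str, tuple[int, int]] = {
    "basic": (0, 13),
    "helix1": (13, 28),
    "loop": (28, 36),
    "helix2": (36, 51),
}

# Rule-label -> profile column.  All four sit inside the basic region.
NAMED_POSITIONS: dict[str, int] = {
    "H/K-1": 3,
    "E-2": 6,
    "R-4": 10,
    "R-5": 12,
}

#        basic(13)     helix1(15)      loop(8)  helix2(15)
CONSENSUS = "NREHRRERRARQR" "LERISKAIDYLQELL" "GSNDKGPE" "VKATLSKIDTLRMAV"
assert len(CONSENSUS) == 51

# Eight aligned rows: the consensus plus variants with substitutions
# concentrated in the helices/loop (the basic region is the most
# conserved in real families) and one row with a 2-column loop gap.
SEED_ALIGNMENT: tuple[str, ...] = (
    "NREHRRERRARQR" "LERISKAIDYLQELL" "GSNDKGPE" "VKATLSKIDTLRMAV",
    "NRDHRRERRARQR" "LERMSKAVDYLQELL" "GSNDKGPE" "VKATLSKIETLRMAV",
    "NREHRKERRARQR" "IERISKAIDYLRELL" "GTNDKGPE" "VKSTLSKIDTLRLAV",
    "SREHRRERRARQR" "LERISRAIDYLQDLL" "GSNEKGPE" "IKATLSKIDTLRMAI",
    "NREHRRERKARQR" "LEKISKAIDFLQELL" "GSND--PE" "VKATLAKIDTLRMAV",
    "NREHRRDRRARQR" "LQRISKAIDYLQELM" "ASNDKGPE" "VKATLSKVDTLRMAV",
    "NKEHRRERRARQR" "LERISKALDYLQELL" "GSNDKGSE" "VRATLSKIDTLKMAV",
    "NREHRRERRARQR" "LERVSKAIDYLQELL" "GSNDRGPE" "VKATLSKIDSLRMAV",
)
assert all(len(row) == len(CONSENSUS) for row in SEED_ALIGNMENT)

# Canonical intron positions inside the domain-encoding CDS, as
# nucleotide offsets from the domain start: position 1 at the
# basic/helix1 junction, position 2 in the loop, position 3 in helix2.
CANONICAL_INTRON_OFFSETS: tuple[int, int, int] = (39, 93, 129)

# Score threshold for domain hits, calibrated as the 99th percentile of
# profile scores over 1,000 residue shuffles of the consensus
# (calibrate_score_threshold(profile, n_shuffles=1000, seed=0)); the
# value is frozen here so the packaged profile is constant.
DEFAULT_SCORE_THRESHOLD: float = 0.3066
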