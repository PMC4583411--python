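"""The curated IAPS image set used in the original valence study.

95 images of the "People & Daily Activity" visual class, after removing
images whose valence is strongly gender-disputed: 47 neutral, 24
pleasant and 24 unpleasant, labelled by mean SAM valence (neutral band
3.8-5.8).  IAPS image identifiers only — no image content or affective
norms are redistributed here.
"""

from __future__ import annotations

NEUTRAL_IDS = (
    "2020", "2102", "2104", "2130", "2190", "2200", "2271", "2272", "2280",
    "2210", "2214", "2215", "2220", "2221", "2230", "2305", "2357", "2372",
    "2383", "2385", "2393", "2396", "2397", "2435", "2441", "2485", "2487",
    "2491", "2493", "2495", "2499", "2512", "2513", "2516", "2520", "2595",
    "2635", "2690", "2704", "2749", "2770", "2780", "2795", "2830", "2840",
    "2870", "7506",
)

PLEASANT_IDS = (
    "1340", "1999", "2000", "2010", "2037", "2091", "2092", "2154", "2222",
    "2304", "2339", "2340", "2341", "2358", "2362", "2391", "2501", "2530",
    "2620", "2650", "4617", "5410", "7325", "8497",
)

UNPLEASANT_IDS = (
    "2095", "2110", "2120", "2141", "2205", "2276", "2278", "2490", "2590",
    "2691", "2710", "2750", "3500", "3530", "4621", "6243", "6313", "6315",
    "6360", "6370", "6530", "6550", "6560", "6561",
)

CURATED_SET: dict[str, tuple[str, ...]] = {
    "unpleasant": UNPLEASANT_IDS,
    "neutral": NEUTRAL_IDS,
    "pleasant": PLEASANT_IDS,
}


def curated_class_counts() -> dict[str, int]:
    """Number of curated images per valence class (plus the total)."""
    counts = {cls: len(ids) for cls, ids in CURATED_SET.items()}
    counts["total"] = sum(len(ids) for ids in CURATED_SET.values())
    return counts
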