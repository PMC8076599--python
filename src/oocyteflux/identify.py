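"""Three-tier library identification of detected GC-MS peaks.

A peak is matched against library candidates inside a retention-index window
and assigned the highest criterion it supports:

* **Criterion 1** — retention index within +-3.0 RI units of the library
  value, at least four characteristic library ions present, forward spectral
  similarity >= 850/1000, deconvolved abundance >= 500 and peak symmetry.
* **Criterion 2** — criterion 1 plus confirmation by an authentic standard
  run in the same batch (available for the canonical amino acids).
* **Criterion 3** — reverse (head-to-tail) match score >= 700/999 with the
  two most abundant library ions present.

Spectral similarity is a weighted cosine with weights I^0.5 * m/z. The major
trimethylsilyl reagent ions at m/z 73 and 147 carry no identity information
and are excluded from all decisive comparisons. The "min similarity product
= 60%" parameter acts as the candidate-admission gate (forward score >= 600)
before the criterion tests; the "MST centroid distance = +-1 RI" parameter is
the merge radius used when grouping the same unidentified component across
samples into one matrix row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["IdentificationParams", "IdentifiedMetabolite", "forward_score",
           "reverse_score", "qualifier_check", "identify_peak",
           "map_conversion_products", "CONVERSION_PARENTS"]

#: Known on-column conversion products and their parent metabolites.
CONVERSION_PARENTS = {
    "Ornithine": ("Arginine",),
    "Pyroglutamic acid": ("Glutamic acid", "Glutamine"),
}


@dataclass(frozen=True)
class IdentificationParams:
    ri_window: float = 4.0
    centroid_distance: float = 1.0       # RI merge radius across samples
    min_area: float = 1000.0
    qualifier_ratio_tolerance: float = 0.30
    min_correct_qualifiers: int = 2
    max_avg_ratio_error: float = 0.70
    min_similarity_product: float = 600.0  # admission gate, /1000
    criterion1_ri_tol: float = 3.0
    criterion1_min_mz_peaks: int = 4
    criterion1_min_score: float = 850.0
    criterion1_min_abundance: float = 500.0
    criterion3_min_reverse: float = 700.0
    min_symmetry: float = 0.5
    excluded_mz: frozenset = frozenset({73, 147})


@dataclass
class IdentifiedMetabolite:
    peak: object
    name: str | None
    criterion: str                      # "1" | "2" | "3" | "unidentified"
    forward_score: float = 0.0
    reverse_score: float = 0.0
    ri_error: float = float("nan")
    qualifier_pass: bool = False
    standard_confirmed: bool = False
    is_conversion_product: bool = False
    conversion_parents: tuple[str, ...] = field(default_factory=tuple)


def _clean(spectrum, excluded) -> dict[int, float]:
    return {int(mz): float(i) for mz, i in spectrum
            if int(mz) not in excluded and i > 0}


def _weights(spec: dict[int, float]) -> dict[int, float]:
    # weighted-cosine weights: sqrt intensity de-emphasises dominant ions,
    # m/z emphasises the structurally informative high-mass fragments
    return {mz: (i ** 0.5) * mz for mz, i in spec.items()}


def _cosine(wq: dict[int, float], wl: dict[int, float], support) -> float:
    mzs = sorted(support)
    q = np.array([wq.get(mz, 0.0) for mz in mzs])
    l = np.array([wl.get(mz, 0.0) for mz in mzs])
    nq, nl = np.linalg.norm(q), np.linalg.norm(l)
    if nq == 0 or nl == 0:
        return 0.0
    return float(np.dot(q, l) / (nq * nl))


def forward_score(query_spectrum, library_spectrum,
                  params: IdentificationParams | None = None) -> float:
    """Weighted-cosine similarity over the union of ions, scaled to 0..1000.
    A self-match scores exactly 1000; disjoint spectra score 0."""
    params = params or IdentificationParams()
    q = _clean(query_spectrum, params.excluded_mz)
    l = _clean(library_spectrum, params.excluded_mz)
    if not q or not l:
        return 0.0
    return 1000.0 * _cosine(_weights(q), _weights(l), set(q) | set(l))


def reverse_score(query_spectrum, library_spectrum,
                  params: IdentificationParams | None = None) -> float:
    """Head-to-tail match: the same weighted cosine restricted to library
    ions only (contaminating query-only ions are ignored), scaled to 0..999."""
    params = params or IdentificationParams()
    q = _clean(query_spectrum, params.excluded_mz)
    l = _clean(library_spectrum, params.excluded_mz)
    if not q or not l:
        return 0.0
    return 999.0 * _cosine(_weights(q), _weights(l), set(l))


def qualifier_check(query_spectrum, library_record,
                    params: IdentificationParams | None = None):
    """Validate qualifier-ion ratios against the library entry.

    Ratios are taken to the quantifier ion. Pass requires at least
    ``min_correct_qualifiers`` ions with relative ratio error within the
    tolerance (30%) AND a mean error no larger than ``max_avg_ratio_error``
    (70%). Returns ``(passed, per_ion_errors)``.
    """
    params = params or IdentificationParams()
    quant = library_record.quantifier_mz
    lib = _clean(library_record.spectrum, params.excluded_mz)
    query = _clean(query_spectrum, params.excluded_mz)
    if quant not in lib:
        raise ValueError(f"{library_record.name}: quantifier excluded or absent")
    if quant not in query or query[quant] <= 0:
        return False, {"reason": "quantifier absent in query"}
    # qualifiers: the most intense non-quantifier library ions
    quals = sorted((mz for mz in lib if mz != quant),
                   key=lambda mz: -lib[mz])
    if len(quals) < params.min_correct_qualifiers:
        raise ValueError(f"{library_record.name}: needs >= "
                         f"{params.min_correct_qualifiers} qualifier ions")
    errors = {}
    for mz in quals:
        lib_ratio = lib[mz] / lib[quant]
        q_ratio = query.get(mz, 0.0) / query[quant]
        errors[mz] = abs(q_ratio - lib_ratio) / lib_ratio
    n_correct = sum(e <= params.qualifier_ratio_tolerance
                    for e in errors.values())
    mean_error = float(np.mean(list(errors.values())))
    passed = (n_correct >= params.min_correct_qualifiers
              and mean_error <= params.max_avg_ratio_error)
    return passed, errors


def _top_ions(lib: dict[int, float], n: int = 2) -> list[int]:
    return sorted(lib, key=lambda mz: -lib[mz])[:n]


def identify_peak(peak, library, params: IdentificationParams | None = None,
                  standard_confirmed_names=frozenset()) -> IdentifiedMetabolite:
    """Assign the best library identity to a detected peak.

    ``peak`` needs ``assigned_ri``, ``spectrum``, ``height`` and (optionally)
    ``symmetry``. ``standard_confirmed_names`` is the set of metabolites whose
    identity was confirmed by a same-batch authentic-standard run; criterion 1
    hits on these are promoted to criterion 2. Tie-break among passing
    candidates: criterion tier, then forward score, then smallest RI error.
    """
    params = params or IdentificationParams()
    if peak.assigned_ri is None:
        raise ValueError("peak has no assigned retention index")
    query = list(peak.spectrum)
    symmetry = getattr(peak, "symmetry", 1.0)
    height = getattr(peak, "height", 0.0)

    candidates = []
    for rec in library:
        variants = getattr(rec, "tms_variants", None) or \
            [("main", 1.0, rec.retention_index)]
        ri_err = min(abs(peak.assigned_ri - vri) for _, _, vri in variants)
        if ri_err > params.ri_window:
            continue
        fwd = forward_score(query, rec.spectrum, params)
        if fwd < params.min_similarity_product:
            continue
        rev = reverse_score(query, rec.spectrum, params)
        lib_clean = _clean(rec.spectrum, params.excluded_mz)
        query_mzs = {mz for mz, i in query if i > 0}
        n_present = sum(mz in query_mzs for mz in lib_clean)
        qual_pass, _ = qualifier_check(query, rec, params)

        crit1 = (ri_err <= params.criterion1_ri_tol
                 and n_present >= params.criterion1_min_mz_peaks
                 and fwd >= params.criterion1_min_score
                 and height >= params.criterion1_min_abundance
                 and symmetry >= params.min_symmetry)
        crit2 = crit1 and rec.name in standard_confirmed_names
        crit3 = (not crit1
                 and rev >= params.criterion3_min_reverse
                 and all(mz in query_mzs for mz in _top_ions(lib_clean)))
        if crit2:
            tier = "2"
        elif crit1:
            tier = "1"
        elif crit3:
            tier = "3"
        else:
            continue
        candidates.append((tier, fwd, rev, ri_err, qual_pass, rec))

    if not candidates:
        return IdentifiedMetabolite(peak=peak, name=None,
                                    criterion="unidentified")
    candidates.sort(key=lambda c: (-int(c[0] in ("1", "2")) - (c[0] == "2"),
                                   -c[1], c[3]))
    tier, fwd, rev, ri_err, qual_pass, rec = candidates[0]
    ident = IdentifiedMetabolite(
        peak=peak, name=rec.name, criterion=tier, forward_score=fwd,
        reverse_score=rev, ri_error=ri_err, qualifier_pass=qual_pass,
        standard_confirmed=(tier == "2"))
    return map_conversion_products([ident])[0]


def map_conversion_products(identified):
    """Flag known on-column conversion products with their parent names.

    Ornithine (from arginine) and pyroglutamate (from glutamate/glutamine)
    stay in all outputs; the flag only annotates them.
    """
    for ident in identified:
        if ident.name in CONVERSION_PARENTS:
            ident.is_conversion_product = True
            ident.conversion_parents = CONVERSION_PARENTS[ident.name]
    return identified
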