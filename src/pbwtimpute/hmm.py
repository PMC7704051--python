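"""Haploid Li & Stephens copying HMM and imputation at untyped markers.

Each target haplotype is modelled as an imperfect mosaic of its selected
reference copying states.  At the T typed markers a forward-backward
pass yields posterior copying probabilities; between typed markers the
state probabilities change approximately linearly over genetic distance,
so the allele probability at an untyped marker is a linear interpolation
of the (sparsified, renormalized) flanking posteriors summed over the
states that carry the alternate allele there.

Transitions follow the usual recombination parameterisation: with S
copying states and a genetic gap of g Morgans between adjacent typed
markers, the switch probability is ``rho = 1 - exp(-4 Ne g / S)``, and a
switch lands on a uniformly chosen state.  Emissions are a fixed
match/mismatch probability of 0.9999/0.0001, absorbing both mutation and
genotyping error.

Sparsification follows the inverse-of-state-count rule: a state's
probability is stored across a typed-marker interval only if it exceeds
1/S at one of the two flanking typed markers.  Stored flank posteriors
are renormalized before interpolation so dosages stay in [0, 1].

Rare untyped variants (alternate frequency < 1/256, i.e. exactly those
stored sparse in the reference container) admit *delayed lazy
imputation*: if no stored flank state carries the alternate allele the
marker is emitted monomorphic with probability exactly 0, skipping the
interpolation; the full computation would return the same 0, so the lazy
path is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imp5 import TAG_SPARSE, Imp5Record, Imp5Store


@dataclass
class HmmParameters:
    """Copying-model parameters.

    ``ne`` is the effective diploid population size (default 20,000, the
    conventional value for human panels); ``min_rho`` floors the switch
    probability so the chain never freezes across zero-cM gaps.
    """

    ne: float = 20000.0
    e_match: float = 0.9999
    e_mismatch: float = 0.0001
    min_rho: float = 1e-9

    def __post_init__(self):
        if not (0 < self.min_rho < 1):
            raise ValueError("min_rho must be in (0, 1)")
        if abs(self.e_match + self.e_mismatch - 1.0) > 1e-12:
            raise ValueError("emission probabilities must sum to 1")


def rho(cm_gap, n_states: int, params: HmmParameters):
    """Per-interval switch probability ``1 - exp(-4 Ne g / S)`` with the
    genetic gap ``g`` in Morgans (``cm_gap`` is in centimorgans)."""
    cm_gap = np.asarray(cm_gap, dtype=float)
    r = -np.expm1(-4.0 * params.ne * (cm_gap / 100.0) / n_states)
    return np.maximum(r, params.min_rho)


def forward_backward(
    target_alleles: np.ndarray,
    state_alleles: np.ndarray,
    cm: np.ndarray,
    params: HmmParameters | None = None,
    n_panel: int | None = None,
) -> np.ndarray:
    """Posterior copying probabilities at every typed marker.

    Parameters
    ----------
    target_alleles
        ``(T,)`` observed target alleles at typed markers.
    state_alleles
        ``(S, T)`` alleles of the selected copying states.
    cm
        ``(T,)`` genetic positions of the typed markers.
    n_panel
        Haplotype count used in the switch-rate denominator.  When the
        S copying states are a PBWT-selected subset of a larger
        reference panel this should be the *panel* size: the subset is
        a computational restriction of the full copying model, and the
        Li & Stephens switch intensity ``4 Ne g / N`` shrinks as the
        panel grows (shared segments lengthen), which is what makes
        accuracy improve with panel size.  Defaults to S (the
        self-contained model on exactly these states).

    Returns
    -------
    ``(T, S)`` posteriors, each row summing to 1.  Uniform initial
    distribution; per-marker rescaling guards against underflow.
    """
    params = params or HmmParameters()
    t_obs = np.asarray(target_alleles, dtype=np.uint8)
    h = np.asarray(state_alleles, dtype=np.uint8)
    if h.ndim != 2 or h.shape[1] != t_obs.shape[0]:
        raise ValueError("state_alleles must be (S, T) matching the target")
    s, t = h.shape
    if s < 1:
        raise ValueError("at least one copying state is required")
    em = np.where(h.T == t_obs[:, None], params.e_match, params.e_mismatch)  # (T, S)
    rhos = rho(np.diff(np.asarray(cm, dtype=float)), n_panel or s, params)

    alpha = np.empty((t, s))
    a = em[0] / s
    alpha[0] = a / a.sum()
    for m in range(1, t):
        r = rhos[m - 1]
        pred = (1.0 - r) * alpha[m - 1] + r / s  # alpha rows are normalized
        a = em[m] * pred
        alpha[m] = a / a.sum()

    post = np.empty((t, s))
    beta = np.ones(s) / s
    post[t - 1] = alpha[t - 1] * beta
    for m in range(t - 2, -1, -1):
        r = rhos[m]
        eb = em[m + 1] * beta
        beta = (1.0 - r) * eb + r / s * eb.sum()
        beta /= beta.sum()
        post[m] = alpha[m] * beta
    post /= post.sum(axis=1, keepdims=True)
    return post


@dataclass
class PosteriorSet:
    """Thresholded copying posteriors for one target haplotype.

    Wraps the dense ``(T, S)`` posterior together with the selected
    state ids and the typed-marker coordinates; exposes the sparsified,
    renormalized per-interval views that interpolation consumes.  With
    ``sparsify=False`` every state is kept (used for oracle checks).
    """

    posterior: np.ndarray  # (T, S)
    states: np.ndarray  # (S,) reference haplotype ids
    typed_pos: np.ndarray  # (T,) bp
    typed_cm: np.ndarray  # (T,)
    sparsify: bool = True
    _tables: tuple = field(default=None, repr=False)

    @property
    def n_states(self) -> int:
        return self.posterior.shape[1]

    @property
    def threshold(self) -> float:
        return 1.0 / self.n_states if self.sparsify else 0.0

    def keep_mask(self) -> np.ndarray:
        """(T, S) bool: posterior exceeds the storage threshold."""
        if not self.sparsify:
            return np.ones_like(self.posterior, dtype=bool)
        keep = self.posterior > self.threshold
        # a tie at exactly 1/S everywhere (e.g. identical states) would
        # empty the stored set; keep the whole row in that degenerate case
        empty = ~keep.any(axis=1)
        keep[empty] = True
        return keep

    def sparse_at(self, m: int) -> dict:
        """Stored state -> posterior at typed marker ``m`` (unnormalized)."""
        keep = self.keep_mask()[m]
        return {
            int(self.states[i]): float(self.posterior[m, i])
            for i in np.nonzero(keep)[0]
        }

    def interp_tables(self):
        """Per-interval renormalized flank posteriors.

        Returns ``(left, right, support)`` with shape ``(T+1, S)``:
        row ``i`` covers untyped positions between typed markers ``i-1``
        and ``i`` (rows 0 and T are the one-sided edge intervals).
        States outside the interval's support are exactly zero.
        """
        if self._tables is not None:
            return self._tables
        post = self.posterior
        t, s = post.shape
        keep = self.keep_mask()
        sup = np.zeros((t + 1, s), dtype=bool)
        sup[0] = keep[0]
        sup[t] = keep[t - 1]
        sup[1:t] = keep[:-1] | keep[1:]
        lidx = np.clip(np.arange(t + 1) - 1, 0, t - 1)
        ridx = np.clip(np.arange(t + 1), 0, t - 1)
        left = np.where(sup, post[lidx], 0.0)
        right = np.where(sup, post[ridx], 0.0)
        left /= left.sum(axis=1, keepdims=True)
        right /= right.sum(axis=1, keepdims=True)
        self._tables = (left, right, sup)
        return self._tables

    def interval_and_weight(self, pos: np.ndarray, cm: np.ndarray):
        """Interval row index and genetic-distance weight for untyped
        markers at ``pos`` (weight 0 at the left flank; edge intervals
        use the nearest typed marker, weight 0)."""
        pos = np.asarray(pos)
        iv = np.searchsorted(self.typed_pos, pos, side="left")
        w = np.zeros(len(pos), dtype=float)
        inner = (iv > 0) & (iv < len(self.typed_pos))
        li = iv[inner] - 1
        span = self.typed_cm[li + 1] - self.typed_cm[li]
        cm = np.asarray(cm, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = (cm[inner] - self.typed_cm[li]) / span
        frac[~np.isfinite(frac)] = 0.0
        w[inner] = np.clip(frac, 0.0, 1.0)
        return iv, w

    def typed_dosages(self, state_alleles: np.ndarray) -> np.ndarray:
        """Haploid alt probability at each typed marker from the full
        (unsparsified) posterior: sum of state posteriors carrying alt."""
        return np.einsum("ts,st->t", self.posterior, state_alleles.astype(np.float64))


def interpolate_dosage(
    flank_left: dict, flank_right: dict, weight: float, alt_carriers
) -> float:
    """Haploid alt probability at one untyped marker.

    ``flank_left`` / ``flank_right`` map stored state -> renormalized
    posterior at the bounding typed markers; the state probability at
    the untyped marker is ``(1 - w) p_left + w p_right`` and the allele
    probability sums those over ``alt_carriers``.
    """
    carriers = set(alt_carriers)
    states = set(flank_left) | set(flank_right)
    d = sum(
        (1.0 - weight) * flank_left.get(s, 0.0) + weight * flank_right.get(s, 0.0)
        for s in states
        if s in carriers
    )
    return min(max(d, 0.0), 1.0)


@dataclass
class ImputedRecord:
    """One output marker: haploid alt probability per requested target."""

    pos: int
    ref: str
    alt: str
    prob: float
    imputed: bool = True


def lazy_impute_target(
    pset: PosteriorSet,
    records,
    positions: np.ndarray,
    cms: np.ndarray,
    lazy: bool = True,
):
    """Stream untyped-marker records for one target, yielding
    :class:`ImputedRecord` in position order.

    ``records`` is an iterable of :class:`Imp5Record` (the streamed
    reference at untyped markers); ``positions``/``cms`` are their
    coordinates.  Rare sparse records whose carriers miss every stored
    flank state short-circuit to probability 0 (delayed lazy
    imputation); this equals the full interpolation exactly, because
    unstored states carry zero renormalized mass.
    """
    left, right, sup = pset.interp_tables()
    iv, w = pset.interval_and_weight(positions, cms)
    pos_of = {int(s): i for i, s in enumerate(pset.states)}
    last_pos = None
    for k, rec in enumerate(records):
        p = int(positions[k])
        if last_pos is not None and p < last_pos:
            raise ValueError("untyped-marker stream out of position order")
        last_pos = p
        i = int(iv[k])
        if lazy and rec.tag == TAG_SPARSE:
            if not any(
                pos_of.get(int(c)) is not None and sup[i, pos_of[int(c)]]
                for c in rec.carriers
            ):
                yield 0.0
                continue
        carriers = rec.carrier_ids()
        d = 0.0
        for c in carriers:
            j = pos_of.get(int(c))
            if j is not None:
                d += (1.0 - w[k]) * left[i, j] + w[k] * right[i, j]
        yield float(min(max(d, 0.0), 1.0))


def impute_target_untyped(
    pset: PosteriorSet,
    store: Imp5Store,
    bitset_chunk: int = 8192,
) -> np.ndarray:
    """Vectorized dosages for one target at every marker of ``store``.

    Agrees with :func:`lazy_impute_target` to numerical round-off.  The
    sparse-record gather only ever touches carriers, and unstored flank
    states contribute exact zeros, so the computation is lazy by
    construction.  Bitset markers are processed in chunks to bound the
    unpacked (markers x states) scratch matrix.
    """
    left, right, sup = pset.interp_tables()
    positions = store.positions
    cms = store.markers["cm"].to_numpy(dtype=float)
    iv, w = pset.interval_and_weight(positions, cms)
    n_u = store.n_markers
    out = np.zeros(n_u, dtype=float)
    if n_u == 0:
        return out
    col = store.columnar()
    pos_of = np.full(store.n, -1, dtype=np.int64)
    pos_of[pset.states] = np.arange(len(pset.states))
    # ---- sparse records: gather carrier contributions
    sp = col["sparse_idx"]
    if len(sp):
        lens = col["carrier_lens"]
        nz_mask = lens > 0
        nz = sp[nz_mask]
        if len(nz):
            keep_carrier = np.repeat(nz_mask, lens)
            cat = col["carriers_cat"][keep_carrier]
            lens_nz = lens[nz_mask]
            seg = np.repeat(np.arange(len(nz)), lens_nz)
            spos = pos_of[cat]
            valid = spos >= 0
            spos_c = np.where(valid, spos, 0)
            ivs = iv[nz][seg]
            ws = w[nz][seg]
            contrib = (1.0 - ws) * left[ivs, spos_c] + ws * right[ivs, spos_c]
            contrib = np.where(valid, contrib, 0.0)
            offsets = np.concatenate([[0], np.cumsum(lens_nz)[:-1]])
            out[nz] = np.add.reduceat(contrib, offsets)
    # ---- bitset records: dense product over states
    bs = col["bitset_idx"]
    if len(bs):
        bits_mat = col["bits_mat"]
        byte_idx = (pset.states >> 3).astype(np.int64)
        bit_sh = (pset.states & 7).astype(np.uint8)
        for lo in range(0, len(bs), bitset_chunk):
            hi = min(lo + bitset_chunk, len(bs))
            rows = bs[lo:hi]
            vals = (bits_mat[lo:hi][:, byte_idx] >> bit_sh) & 1  # (n_b, S)
            wl = (1.0 - w[rows])[:, None] * left[iv[rows]] + w[rows][:, None] * right[
                iv[rows]
            ]
            out[rows] = np.einsum("ms,ms->m", wl, vals.astype(np.float64))
    return np.clip(out, 0.0, 1.0)


def to_diploid(hap1_prob, hap2_prob):
    """Diploid dosage and genotype probabilities from two independent
    haploid alt probabilities."""
    p1 = np.asarray(hap1_prob, dtype=float)
    p2 = np.asarray(hap2_prob, dtype=float)
    ds = p1 + p2
    gp = np.stack(
        [(1 - p1) * (1 - p2), p1 * (1 - p2) + p2 * (1 - p1), p1 * p2], axis=-1
    )
    return ds, gp
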