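"""Mutational-signature analysis: catalogs, NMF extraction, annotation.

Single-base substitutions are classified into the 96 trinucleotide-context
channels (pyrimidine-strand convention), doublet substitutions into the 78
canonical DBS channels and small insertions/deletions into the 83 ID
channels (length, repeat-unit and microhomology bins). Per-sample channel
counts form a catalog matrix; latent signatures are extracted by
non-negative matrix factorisation (Frobenius objective, multiplicative
updates, multiple random restarts), annotated against a reference set by
cosine similarity, and per-sample exposures are attributed by non-negative
least squares.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples
from statsmodels.stats.multitest import multipletests

from .io import Cohort

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"


class ChannelError(ValueError):
    """Raised when a variant cannot be assigned to a mutation channel."""


def revcomp(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise ChannelError(f"non-ACGT base in {seq!r}") from exc


# ---------------------------------------------------------------------------
# SBS-96

_PYRIMIDINE_SUBS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]

#: The 96 trinucleotide channels in COSMIC order (grouped by substitution).
SBS96_CHANNELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in _PYRIMIDINE_SUBS
    for five in _BASES
    for three in _BASES
)


def classify_sbs96(ref: str, alt: str, context5: str, context3: str) -> str:
    """Trinucleotide channel of a single-base substitution.

    Purine-reference mutations are reverse-complemented so every channel is
    reported on the pyrimidine strand (ref C or T). ``context5``/``context3``
    may be longer than one base; only the adjacent base is used.
    """
    for name, value in (("ref", ref), ("alt", alt)):
        if len(value) != 1 or value not in _BASES:
            raise ChannelError(f"{name} must be a single ACGT base, got {value!r}")
    if ref == alt:
        raise ChannelError("ref and alt are identical")
    if not context5 or not context3:
        raise ChannelError("SBS-96 classification needs one flanking base on each side")
    five, three = context5[-1], context3[0]
    if five not in _BASES or three not in _BASES:
        raise ChannelError(f"non-ACGT flanking base: {five!r}/{three!r}")
    if ref in "AG":  # purine reference: flip to the pyrimidine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        five, three = _COMPLEMENT[three], _COMPLEMENT[five]
    return f"{five}[{ref}>{alt}]{three}"


# ---------------------------------------------------------------------------
# DBS-78

#: Canonical reference dinucleotides and their alternate sets (COSMIC DBS-78).
_DBS78_TABLE = {
    "AC": ["CA", "CG", "CT", "GA", "GG", "GT", "TA", "TG", "TT"],
    "AT": ["CA", "CC", "CG", "GA", "GC", "TA"],
    "CC": ["AA", "AG", "AT", "GA", "GG", "GT", "TA", "TG", "TT"],
    "CG": ["AT", "GC", "GT", "TA", "TC", "TT"],
    "CT": ["AA", "AC", "AG", "GA", "GC", "GG", "TA", "TC", "TG"],
    "GC": ["AA", "AG", "AT", "CA", "CG", "TA"],
    "TA": ["AT", "CG", "CT", "GC", "GG", "GT"],
    "TC": ["AA", "AG", "AT", "CA", "CG", "CT", "GA", "GG", "GT"],
    "TG": ["AA", "AC", "AT", "CA", "CC", "CT", "GA", "GC", "GT"],
    "TT": ["AA", "AC", "AG", "CA", "CC", "CG", "GA", "GC", "GG"],
}

DBS78_CHANNELS = tuple(
    f"{ref}>{alt}" for ref, alts in _DBS78_TABLE.items() for alt in alts
)
_DBS78_SET = frozenset(DBS78_CHANNELS)


def classify_dbs78(ref_dinuc: str, alt_dinuc: str) -> str:
    """Canonical DBS-78 channel; reverse-complement pairs are collapsed."""
    for name, value in (("ref", ref_dinuc), ("alt", alt_dinuc)):
        if len(value) != 2 or any(b not in _BASES for b in value):
            raise ChannelError(f"{name} must be a 2-base ACGT string, got {value!r}")
    n_changed = sum(r != a for r, a in zip(ref_dinuc, alt_dinuc))
    if n_changed != 2:
        raise ChannelError(
            f"{ref_dinuc}>{alt_dinuc} changes {n_changed} position(s); a doublet "
            "substitution must change both"
        )
    label = f"{ref_dinuc}>{alt_dinuc}"
    if label in _DBS78_SET:
        return label
    flipped = f"{revcomp(ref_dinuc)}>{revcomp(alt_dinuc)}"
    if flipped in _DBS78_SET:
        return flipped
    raise ChannelError(f"unclassifiable doublet substitution {label}")  # pragma: no cover


# ---------------------------------------------------------------------------
# ID-83

def _id83_channels() -> tuple[str, ...]:
    chans: list[str] = []
    for base in ("C", "T"):
        chans += [f"1:Del:{base}:{i}" for i in range(6)]
    for base in ("C", "T"):
        chans += [f"1:Ins:{base}:{i}" for i in range(6)]
    for length in (2, 3, 4, 5):
        chans += [f"{length}:Del:R:{i}" for i in range(6)]
    for length in (2, 3, 4, 5):
        chans += [f"{length}:Ins:R:{i}" for i in range(6)]
    for length, max_mh in ((2, 1), (3, 2), (4, 3), (5, 5)):
        chans += [f"{length}:Del:M:{i}" for i in range(1, max_mh + 1)]
    return tuple(chans)


#: The 83 indel channels (SigProfiler-style labels). For deletions the final
#: number is (repeat units - 1) capped at 5; for insertions it is the number
#: of pre-existing copies capped at 5; for microhomology it is the homology
#: length capped at min(deletion length - 1, 5).
ID83_CHANNELS = _id83_channels()
assert len(ID83_CHANNELS) == 83


def _adjacent_copies(seq: str, context5: str, context3: str) -> int:
    """Full adjacent copies of ``seq`` in the flanking reference sequence."""
    L = len(seq)
    copies = 0
    i = 0
    while context3[i : i + L] == seq and len(context3) >= i + L:
        copies += 1
        i += L
    j = len(context5)
    while j - L >= 0 and context5[j - L : j] == seq:
        copies += 1
        j -= L
    return copies


def _microhomology(seq: str, context5: str, context3: str) -> int:
    """Longest partial match of the deleted sequence with its flanks."""
    L = len(seq)
    right = 0
    for m in range(min(L - 1, len(context3)), 0, -1):
        if context3[:m] == seq[:m]:
            right = m
            break
    left = 0
    for m in range(min(L - 1, len(context5)), 0, -1):
        if context5[-m:] == seq[L - m :]:
            left = m
            break
    return max(left, right)


def classify_id83(ref: str, alt: str, context5: str, context3: str) -> str:
    """ID-83 channel of a small insertion or deletion.

    ``ref`` is the deleted sequence and ``alt`` ``"-"`` for deletions;
    ``ref`` is ``"-"`` and ``alt`` the inserted sequence for insertions
    (MAF dash convention). Flanking context is required on both sides.
    """
    if not context5 or not context3:
        raise ChannelError("ID-83 classification needs flanking context on both sides")
    is_del = alt in ("-", "")
    is_ins = ref in ("-", "")
    if is_del == is_ins:
        raise ChannelError(f"not a simple indel: ref={ref!r} alt={alt!r}")
    seq = ref if is_del else alt
    if any(b not in _BASES for b in seq):
        raise ChannelError(f"non-ACGT base in indel sequence {seq!r}")
    kind = "Del" if is_del else "Ins"
    L = len(seq)
    size = min(L, 5)

    if L == 1:
        base = seq
        run = 1 if is_del else 0  # the deleted base itself counts toward the run
        j = len(context5)
        while j >= 1 and context5[j - 1] == base:
            run += 1
            j -= 1
        i = 0
        while i < len(context3) and context3[i] == base:
            run += 1
            i += 1
        if base in "AG":
            base = _COMPLEMENT[base]
        bin_ = min(run - 1 if is_del else run, 5)
        return f"1:{kind}:{base}:{bin_}"

    copies = _adjacent_copies(seq, context5, context3)
    if is_ins:
        return f"{size}:Ins:R:{min(copies, 5)}"
    if copies >= 1:  # repeat-first tie break (COSMIC convention)
        return f"{size}:Del:R:{min(copies, 5)}"
    mh = _microhomology(seq, context5, context3)
    if mh >= 1:
        return f"{size}:Del:M:{min(mh, size - 1 if L < 6 else 5, 5)}"
    return f"{size}:Del:R:0"


# ---------------------------------------------------------------------------
# Catalog construction

CATALOG_CHANNELS = {
    "SBS96": SBS96_CHANNELS,
    "DBS78": DBS78_CHANNELS,
    "ID83": ID83_CHANNELS,
}


def build_catalog(cohort: Cohort, kind: str = "SBS96") -> pd.DataFrame:
    """Samples x channels count matrix for one catalog kind.

    Records of the right variant type that lack the context needed for
    classification are skipped with a warning; the skip count is stored in
    ``result.attrs["n_skipped"]``.
    """
    if kind not in CATALOG_CHANNELS:
        raise ValueError(f"unknown catalog kind {kind!r}")
    channels = CATALOG_CHANNELS[kind]
    muts = cohort.mutations
    if kind == "SBS96":
        cand = muts[muts["variant_type"] == "SNP"]
    elif kind == "DBS78":
        cand = muts[muts["variant_type"] == "DNP"]
    else:
        cand = muts[muts["variant_type"].isin(["INS", "DEL"])]

    samples = cohort.sample_ids
    counts = pd.DataFrame(0, index=pd.Index(samples, name="sample_id"), columns=list(channels))
    n_skipped = 0
    for row in cand.itertuples(index=False):
        try:
            if kind == "SBS96":
                label = classify_sbs96(row.ref_allele, row.alt_allele, row.context5, row.context3)
            elif kind == "DBS78":
                label = classify_dbs78(row.ref_allele, row.alt_allele)
            else:
                label = classify_id83(row.ref_allele, row.alt_allele, row.context5, row.context3)
        except ChannelError:
            n_skipped += 1
            continue
        counts.at[row.sample_id, label] += 1
    if n_skipped:
        warnings.warn(
            f"{kind} catalog: skipped {n_skipped} record(s) lacking usable context",
            stacklevel=2,
        )
    counts.attrs["kind"] = kind
    counts.attrs["n_skipped"] = n_skipped
    return counts


# ---------------------------------------------------------------------------
# NMF extraction

class SignatureNMF(BaseEstimator):
    """Signature extraction by NMF with multiplicative updates.

    Factorises a nonnegative catalog ``X`` (samples x channels) as
    ``X ~ exposures @ signatures.T`` minimising the Frobenius
    reconstruction error, keeping the best of ``n_restarts`` random
    initialisations. Signatures are column-normalised to sum to 1 with the
    scale pushed into the exposures, so exposure rows are on the
    mutation-count scale.

    Parameters
    ----------
    n_signatures : int
        Rank of the factorisation.
    n_restarts : int, default 20
        Random initialisations; the restart with the lowest final objective
        wins.
    max_iter : int, default 2000
        Multiplicative-update iterations per restart.
    tol : float, default 1e-6
        Relative objective decrease below which a restart stops early.
    random_state : int or None
        Seed for the restart initialisations.

    Attributes
    ----------
    signatures_ : ndarray (n_channels, n_signatures)
        Column-stochastic signature matrix.
    exposures_ : ndarray (n_samples, n_signatures)
    reconstruction_err_ : float
        Frobenius norm of ``X - exposures @ signatures.T``.
    objective_history_ : ndarray
        Per-iteration objective of the winning restart (non-increasing).
    """

    def __init__(self, n_signatures: int = 2, n_restarts: int = 20,
                 max_iter: int = 2000, tol: float = 1e-6,
                 random_state: int | None = None):
        self.n_signatures = n_signatures
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    @staticmethod
    def _mu_factorize(X, k, rng, max_iter, tol):
        n, m = X.shape
        scale = np.sqrt(X.mean() / k) if X.mean() > 0 else 1.0
        W = rng.uniform(0.1, 1.0, size=(n, k)) * scale
        H = rng.uniform(0.1, 1.0, size=(k, m)) * scale
        eps = 1e-12
        history = []
        prev = None
        for _ in range(max_iter):
            H *= (W.T @ X) / (W.T @ W @ H + eps)
            W *= (X @ H.T) / (W @ (H @ H.T) + eps)
            obj = np.linalg.norm(X - W @ H)
            history.append(obj)
            if prev is not None and prev - obj <= tol * max(prev, 1.0):
                break
            prev = obj
        return W, H, np.asarray(history)

    def fit(self, X, y=None):
        X = self._validate_catalog(X)
        n, m = X.shape
        k = self.n_signatures
        if k < 1 or k > min(n, m):
            raise ValueError(f"n_signatures={k} outside [1, min(n_samples, n_channels)]")
        if not np.any(X):
            raise ValueError("all-zero catalog: nothing to factorise")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_restarts):
            W, H, history = self._mu_factorize(X, k, rng, self.max_iter, self.tol)
            if best is None or history[-1] < best[2][-1]:
                best = (W, H, history)
        W, H, history = best
        col = H.sum(axis=1)  # push signature scale into exposures
        col[col == 0] = 1.0
        self.signatures_ = (H / col[:, None]).T
        self.exposures_ = W * col[None, :]
        self.objective_history_ = history
        self.reconstruction_err_ = float(history[-1])
        self.n_iter_ = len(history)
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).exposures_

    def transform(self, X):
        """Attribute exposures for new samples onto the fitted signatures (NNLS)."""
        X = self._validate_catalog(X)
        return _nnls_exposures(X, self.signatures_)

    @staticmethod
    def _validate_catalog(X):
        X = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("catalog must be a 2-D samples x channels matrix")
        if (X < 0).any():
            raise ValueError("catalog counts must be nonnegative")
        return X


def extract_signatures(catalog: pd.DataFrame, k: int, n_restarts: int = 20,
                       seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract ``k`` signatures from a catalog DataFrame.

    Returns ``(signatures, exposures)``: signatures indexed by channel with
    columns ``S1..Sk`` (each summing to 1), exposures indexed by sample with
    an extra ``dominant_signature`` column (argmax of relative exposure).
    """
    model = SignatureNMF(n_signatures=k, n_restarts=n_restarts, random_state=seed).fit(catalog)
    sig_cols = [f"S{i + 1}" for i in range(k)]
    signatures = pd.DataFrame(model.signatures_, index=catalog.columns, columns=sig_cols)
    exposures = pd.DataFrame(model.exposures_, index=catalog.index, columns=sig_cols)
    exposures["dominant_signature"] = dominant_signature(exposures[sig_cols])
    signatures.attrs["reconstruction_err"] = model.reconstruction_err_
    signatures.attrs["n_restarts"] = n_restarts
    signatures.attrs["seed"] = seed
    return signatures, exposures


def dominant_signature(exposures: pd.DataFrame) -> pd.Series:
    """Per-sample argmax of relative exposure; samples with no mutations get 'none'."""
    total = exposures.sum(axis=1)
    dom = exposures.idxmax(axis=1)
    dom[total == 0] = "none"
    return dom


def select_k(catalog: pd.DataFrame, k_range, seed: int | None = None,
             n_restarts: int = 8, silhouette_threshold: float = 0.8) -> dict:
    """Choose the number of signatures by restart stability.

    For each candidate ``k``, ``n_restarts`` factorisations are run, each on
    a multinomial bootstrap of the catalog (per-sample counts resampled from
    the observed channel profile) so that components which merely fit noise
    do not reappear across restarts. The pooled restart signatures are
    clustered into ``k`` groups and stability is the *minimum* per-cluster
    mean cosine silhouette — a signature set only counts as reproducible
    when every one of its components is. The chosen ``k`` is the largest
    candidate reaching the threshold (``k=1`` is defined as perfectly
    stable).
    """
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("k_range is empty")
    rng = np.random.default_rng(seed)
    X = SignatureNMF._validate_catalog(catalog)
    rows = []
    for k in k_range:
        sigs = []
        errs = []
        for _ in range(n_restarts):
            totals = X.sum(axis=1)
            Xb = np.vstack([
                rng.multinomial(int(t), row / t) if t > 0 else row
                for row, t in zip(X, totals)
            ]).astype(float)
            sub = SignatureNMF(
                n_signatures=k, n_restarts=1,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(Xb)
            sigs.append(sub.signatures_.T)  # k rows of channel profiles
            errs.append(float(np.linalg.norm(X - sub.exposures_ @ sub.signatures_.T)))
        pooled = np.vstack(sigs)
        norms = np.linalg.norm(pooled, axis=1, keepdims=True)
        pooled = pooled / np.where(norms > 0, norms, 1.0)
        if k == 1:
            sil = 1.0
        else:
            labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(pooled)
            if len(set(labels)) < 2:
                sil = 0.0
            else:
                per_point = silhouette_samples(pooled, labels, metric="cosine")
                sil = float(min(per_point[labels == c].mean() for c in set(labels)))
        rows.append({"k": k, "silhouette": sil, "reconstruction_err": float(np.min(errs))})
    table = pd.DataFrame(rows).set_index("k")
    stable = table.index[table["silhouette"] >= silhouette_threshold]
    chosen = int(stable.max()) if len(stable) else int(table["silhouette"].idxmax())
    return {"k": chosen, "table": table}


# ---------------------------------------------------------------------------
# Annotation and attribution

def cosine_annotate(signatures: pd.DataFrame, reference: pd.DataFrame,
                    threshold: float = 0.75) -> pd.DataFrame:
    """Best-matching reference signature for each extracted signature.

    Channels are aligned by label (reordering the reference if needed);
    a best match below the similarity threshold is reported as ``"novel"``.
    """
    if set(signatures.index) != set(reference.index):
        raise ValueError("signature and reference channel labels do not match")
    ref = reference.loc[signatures.index]
    S = signatures.to_numpy(float)
    R = ref.to_numpy(float)
    s_norm = np.linalg.norm(S, axis=0)
    r_norm = np.linalg.norm(R, axis=0)
    sim = (S.T @ R) / np.outer(np.where(s_norm > 0, s_norm, 1), np.where(r_norm > 0, r_norm, 1))
    best_idx = sim.argmax(axis=1)
    rows = []
    for i, col in enumerate(signatures.columns):
        s = float(sim[i, best_idx[i]])
        rows.append({
            "signature": col,
            "best_match": ref.columns[best_idx[i]] if s >= threshold else "novel",
            "similarity": s,
        })
    return pd.DataFrame(rows).set_index("signature")


def _nnls_exposures(X: np.ndarray, signatures: np.ndarray) -> np.ndarray:
    out = np.zeros((X.shape[0], signatures.shape[1]))
    for i in range(X.shape[0]):
        out[i], _ = nnls(signatures, X[i])
    return out


def attribute_exposures(catalog: pd.DataFrame, signatures: pd.DataFrame) -> pd.DataFrame:
    """Per-sample NNLS fit of catalog counts onto fixed signatures.

    Returns exposures with a ``residual`` column (Euclidean norm of the
    unexplained counts) and a ``dominant_signature`` column.
    """
    if list(catalog.columns) != list(signatures.index):
        if set(catalog.columns) != set(signatures.index):
            raise ValueError("catalog channels and signature channels do not match")
        signatures = signatures.loc[catalog.columns]
    X = catalog.to_numpy(float)
    S = signatures.to_numpy(float)
    E = _nnls_exposures(X, S)
    exposures = pd.DataFrame(E, index=catalog.index, columns=signatures.columns)
    exposures["residual"] = np.linalg.norm(X - E @ S.T, axis=1)
    exposures["dominant_signature"] = dominant_signature(
        exposures[signatures.columns]
    )
    return exposures


def signature_clinical_tests(dominant: pd.Series, groupings: dict[str, pd.Series]) -> pd.DataFrame:
    """Fisher tests of dominant-signature membership against binary groupings.

    For every signature x grouping pair, a two-sided Fisher exact test on
    the 2x2 table (dominant vs not) x (arm A vs arm B), with
    Benjamini-Hochberg FDR across all performed tests. Groupings with an
    empty arm are skipped and flagged.
    """
    rows = []
    sig_levels = [s for s in dominant.unique() if s != "none"]
    for gname, labels in groupings.items():
        common = dominant.index.intersection(labels.index)
        lab = labels.loc[common]
        lab = lab[lab.isin(["A", "B"])]
        dom = dominant.loc[lab.index]
        arms = lab.value_counts()
        skipped = arms.get("A", 0) == 0 or arms.get("B", 0) == 0
        for sig in sorted(sig_levels):
            if skipped:
                rows.append({"signature": sig, "grouping": gname, "skipped": True,
                             "odds_ratio": np.nan, "p": np.nan})
                continue
            a = int(((dom == sig) & (lab == "A")).sum())
            b = int(((dom == sig) & (lab == "B")).sum())
            c = int(((dom != sig) & (lab == "A")).sum())
            d = int(((dom != sig) & (lab == "B")).sum())
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append({"signature": sig, "grouping": gname, "skipped": False,
                         "a": a, "b": b, "c": c, "d": d,
                         "odds_ratio": float(odds), "p": float(p)})
    result = pd.DataFrame(rows)
    tested = result[~result["skipped"]].index if len(result) else []
    result["fdr"] = np.nan
    if len(tested):
        result.loc[tested, "fdr"] = multipletests(result.loc[tested, "p"], method="fdr_bh")[1]
    return result
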