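"""Tail probabilities of weighted chi-square mixtures (Davies' algorithm).

Computes P(sum_j lambda_j * chi2_1 > q) by numerical inversion of the
characteristic function using error-bounded midpoint summation: a truncation
point is located from an explicit bound on the neglected tail of the
inversion integral, the summation interval is chosen from the spread of the
distribution, and the integrand is summed on a uniform grid. Accuracy is
controlled by ``acc`` (absolute). Raises :class:`DaviesFailure` when the
term budget would be exceeded, so callers can fall back to moment matching.

Central case only (unit degrees of freedom, no noncentrality, no Gaussian
component), which is all the aggregation tests need.
"""

from __future__ import annotations

import math

import numpy as np


class DaviesFailure(Exception):
    """Requested accuracy not attainable within the term budget."""


def _log1(x: float, first: bool) -> float:
    """log(1+x) or log(1+x)-x."""
    return math.log1p(x) if first else math.log1p(x) - x


_LOG28 = math.log(2.0) / 8.0


class _QF:
    def __init__(self, lb: np.ndarray, c: float, acc: float, lim: int):
        self.lb = np.asarray(lb, dtype=float)
        self.c = float(c)
        self.acc = acc
        self.lim = lim
        self.count = 0
        self.sigsq = 0.0  # accumulated convergence-factor variance
        self.intl = 0.0
        self.ersm = 0.0
        self.fail = False
        self.lmax = max(self.lb.max(), 0.0)
        self.lmin = min(self.lb.min(), 0.0)
        self.mean = float(self.lb.sum())
        self.sd = math.sqrt(2.0 * float(np.sum(self.lb**2)))

    def _counter(self, k: int = 1) -> None:
        self.count += k
        if self.count > self.lim:
            raise DaviesFailure("term budget exceeded")

    # -- error bound of neglected integral tail beyond u --------------------
    def _errbd(self, u: float) -> tuple[float, float]:
        self._counter()
        xconst = u * self.sigsq
        sum1 = u * xconst
        u2 = 2.0 * u
        x = u2 * self.lb
        y = 1.0 - x
        xconst += float(np.sum(self.lb / y))
        sum1 += float(np.sum(x**2 / y)) + float(np.sum(np.log1p(-x) + x))
        bd = math.exp(-0.5 * sum1) if -0.5 * sum1 > -700 else 0.0
        return bd, xconst

    # -- c.f. truncation error bound at u -----------------------------------
    def _truncation(self, u: float, tausq: float = 0.0) -> float:
        self._counter()
        sum2 = (self.sigsq + tausq) * u * u
        prod1 = 2.0 * sum2
        u2 = 2.0 * u
        x = (u2 * self.lb) ** 2
        big = x > 1.0
        s = int(np.sum(big))
        prod2 = float(np.sum(np.log(x[big]))) if s else 0.0
        prod3 = float(np.sum(np.log1p(x[big]))) if s else 0.0
        prod1 += float(np.sum(np.log1p(x[~big])))
        sum1 = 0.0  # no noncentrality
        prod2 += prod1
        prod3 += prod1
        xx = math.exp(-sum1 - 0.25 * prod2) / math.pi if -sum1 - 0.25 * prod2 > -700 else 0.0
        yy = math.exp(-sum1 - 0.25 * prod3) / math.pi if -sum1 - 0.25 * prod3 > -700 else 0.0
        err1 = 1.0 if s == 0 else xx * 2.0 / s
        err2 = 2.5 * yy if prod3 > 1.0 else 1.0
        err1 = min(err1, err2)
        xh = 0.5 * sum2
        err2 = 1.0 if xh <= yy else yy / xh
        return min(err1, err2)

    def _findu(self, utx: float, accx: float) -> float:
        u = utx / 4.0
        if self._truncation(u) > accx:
            u = utx
            while self._truncation(u) > accx:
                u *= 4.0
            utx = u
        else:
            utx = u
            u = u / 4.0
            while self._truncation(u) <= accx:
                utx = u
                u = u / 4.0
        for divis in (2.0, 1.4, 1.2, 1.1):
            u = utx / divis
            if self._truncation(u) <= accx:
                utx = u
        return utx

    # -- distribution range: find x with P(Q > x) (or <) below accx ---------
    def _ctff(self, accx: float, upn: float) -> tuple[float, float]:
        u2 = upn
        u1 = 0.0
        c1 = self.mean
        rb = 2.0 * (self.lmax if u2 > 0.0 else self.lmin)
        u = u2 / (1.0 + u2 * rb)
        bd, c2 = self._errbd(u)
        while bd > accx:
            u1 = u2
            c1 = c2
            u2 *= 2.0
            u = u2 / (1.0 + u2 * rb)
            bd, c2 = self._errbd(u)
        while (c1 - self.mean) / (c2 - self.mean) < 0.9:
            u = (u1 + u2) / 2.0
            bd, xconst = self._errbd(u / (1.0 + u * rb))
            if bd > accx:
                u1 = u
                c1 = xconst
            else:
                u2 = u
                c2 = xconst
        return c2, u2

    def _integrate(
        self, nterm: int, interv: float, tausq: float = 0.0, mainx: bool = True,
        chunk: int = 1 << 18,
    ) -> None:
        self._counter(nterm + 1)
        for start in range(0, nterm + 1, chunk):
            k = np.arange(start, min(start + chunk, nterm + 1), dtype=float)
            u = (k + 0.5) * interv
            x = 2.0 * np.outer(u, self.lb)
            y = x**2
            sum3 = -0.5 * self.sigsq * u**2 - 0.25 * np.sum(np.log1p(y), axis=1)
            z = np.arctan(x)
            sum1 = -2.0 * u * self.c + np.sum(z, axis=1)
            sum2 = np.abs(-2.0 * u * self.c) + np.sum(np.abs(z), axis=1)
            xf = (interv / math.pi) * np.exp(np.maximum(sum3, -700)) / u
            if not mainx:
                xf = xf * (1.0 - np.exp(np.maximum(-0.5 * tausq * u**2, -700)))
            self.intl += float(np.sum(np.sin(0.5 * sum1) * xf))
            self.ersm += float(np.sum(0.5 * sum2 * xf))

    # -- error coefficient for the convergence factor at x -------------------
    def _cfe(self, x: float) -> float:
        self._counter()
        th = np.argsort(-np.abs(self.lb))  # decreasing |lambda|
        axl = abs(x)
        sxl = 1.0 if x > 0.0 else -1.0
        sum1 = 0.0
        r = len(self.lb)
        for j in range(r - 1, -1, -1):
            t = th[j]
            if self.lb[t] * sxl > 0.0:
                lj = abs(self.lb[t])
                axl1 = axl - lj  # unit df, no noncentrality
                axl2 = lj / _LOG28
                if axl1 > axl2:
                    axl = axl1
                else:
                    if axl > axl2:
                        axl = axl2
                    sum1 = (axl - axl1) / lj + j  # + count of remaining terms
                    break
        if sum1 > 100.0 or axl <= 0.0:
            self.fail = True
            return 1.0
        return 2.0 ** (sum1 / 4.0) / (math.pi * axl * axl)

    def tail(self) -> float:
        """P(Q > c)."""
        if self.sd == 0.0:
            return 0.0 if self.c > 0.0 else 1.0
        almx = max(self.lmax, -self.lmin)
        acc1 = self.acc
        utx = self._findu(16.0 / self.sd, 0.5 * acc1)
        # Does a convergence factor help from the start?
        if self.c != 0.0 and almx > 0.07 * self.sd:
            tausq = 0.25 * acc1 / self._cfe(self.c)
            if self.fail:
                self.fail = False
            elif self._truncation(utx, tausq) < 0.2 * acc1:
                self.sigsq += tausq
                utx = self._findu(utx, 0.25 * acc1)
        acc1 *= 0.5
        up = 4.5 / self.sd
        un = -up
        # Main loop: shrink the required term count with auxiliary
        # convergence-factor integrations when necessary.
        while True:
            d1, up = self._ctff(acc1, up)
            d1 -= self.c
            if d1 < 0.0:
                return 0.0  # beyond upper range: tail below acc
            d2, un = self._ctff(acc1, un)
            d2 = self.c - d2
            if d2 < 0.0:
                return 1.0
            intv = 2.0 * math.pi / max(d1, d2)
            xnt = utx / intv
            xntm = 3.0 / math.sqrt(acc1)
            if xnt <= xntm * 1.5:
                break
            if xntm > self.lim - self.count:
                raise DaviesFailure("auxiliary term budget exceeded")
            ntm = int(math.floor(xntm + 0.5))
            intv1 = utx / ntm
            x = 2.0 * math.pi / intv1
            if x <= abs(self.c):
                break
            tausq = 0.33 * acc1 / (1.1 * (self._cfe(self.c - x) + self._cfe(self.c + x)))
            if self.fail:
                self.fail = False
                break
            acc1 *= 0.67
            self._integrate(ntm, intv1, tausq, mainx=False)
            self.sigsq += tausq
            utx = self._findu(utx, 0.25 * acc1)
            acc1 *= 0.75
        if xnt > self.lim - self.count:
            raise DaviesFailure(f"{xnt:.0f} integration terms needed")
        nt = int(math.floor(xnt + 0.5))
        self._integrate(nt, intv, 0.0, mainx=True)
        qfval = 0.5 - self.intl  # P(Q < c)
        return min(max(1.0 - qfval, 0.0), 1.0)


def qf_tail(lambdas: np.ndarray, q: float, acc: float = 1e-9, lim: int = 20_000_000) -> float:
    """P(sum lambda_j chi2_1 > q); raises DaviesFailure if not attainable."""
    return _QF(np.asarray(lambdas, dtype=float), q, acc, lim).tail()
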