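"""Compiled event-driven integration core.

A Dormand-Prince 5(4) adaptive Runge-Kutta stepper specialised to the
two-dimensional hybrid state (theta, theta_dot), with exact handling of
pulse on/off switching times (the integrator lands on them) and
root-localised state events (toe-off, heel strike, fall-back, linkage
cap) via cubic Hermite interpolation and bisection on the interpolant.

Everything here is numba-compiled and operates on plain floats and
preallocated arrays; the public modules wrap these routines in typed
result objects.  Entrainment scans call :func:`sim_walk` (hundreds of
runs x hundreds of strides), which is why this core is compiled.
"""

import numpy as np
from numba import njit

# step termination codes
COMPLETED = 0
FALL_BACK = 1
FLY_OFF = 2
LINKAGE_SINGULARITY = 3
MAXITER = 9

# gating policies for a pulse active at nominal toe-off (psi = mu)
TRUNCATE_AT_MU = 0
EXTEND_WHILE_POSITIVE = 1

_INF = 1.0e300
_MAX_STEPS = 400_000


@njit(cache=True, inline="always")
def _psi(th, L, l, a):
    ac2 = a * a + L * L - 2.0 * a * L * np.sin(th)
    c = (l * l + L * L - ac2) / (2.0 * l * L)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return np.arccos(c)


@njit(cache=True, inline="always")
def _accel(th, thd, ss, extra, m, L, l, g, mu, k, a):
    """Angular acceleration; ss selects single stance, extra is the gated pulse torque."""
    if ss:
        return g / L * np.sin(th)
    psi = _psi(th, L, l, a)
    T = extra
    if psi < mu:
        T += k * (mu - psi)
    s = np.sin(psi)
    if s < 1e-9:
        s = 1e-9
    dpsi = -a * np.cos(th) / (l * s)
    return (m * g * L * np.sin(th) + T * dpsi) / (m * L * L)


@njit(cache=True, inline="always")
def _grf_leading(th, thd, extra, m, L, l, g, mu, k, a):
    """Leading-heel ground reaction force F_B during double stance [N]."""
    psi = _psi(th, L, l, a)
    T = extra
    if psi < mu:
        T += k * (mu - psi)
    s = np.sin(psi)
    if s < 1e-9:
        s = 1e-9
    dpsi = -a * np.cos(th) / (l * s)
    phi = np.arctan2(L * np.cos(th), a - L * np.sin(th))
    FA = -T * dpsi / (L * np.cos(th - phi))
    return m * g * np.cos(th) - m * L * thd * thd - FA * np.sin(phi - th)


@njit(cache=True)
def _dp_step(t, th, thd, h, ss, extra, m, L, l, g, mu, k, a):
    """One Dormand-Prince 5(4) step; returns (th1, thd1, err_norm)."""
    k1t = thd
    k1d = _accel(th, thd, ss, extra, m, L, l, g, mu, k, a)

    y2t = th + h * (0.2 * k1t)
    y2d = thd + h * (0.2 * k1d)
    k2t = y2d
    k2d = _accel(y2t, y2d, ss, extra, m, L, l, g, mu, k, a)

    y3t = th + h * (3.0 / 40.0 * k1t + 9.0 / 40.0 * k2t)
    y3d = thd + h * (3.0 / 40.0 * k1d + 9.0 / 40.0 * k2d)
    k3t = y3d
    k3d = _accel(y3t, y3d, ss, extra, m, L, l, g, mu, k, a)

    y4t = th + h * (44.0 / 45.0 * k1t - 56.0 / 15.0 * k2t + 32.0 / 9.0 * k3t)
    y4d = thd + h * (44.0 / 45.0 * k1d - 56.0 / 15.0 * k2d + 32.0 / 9.0 * k3d)
    k4t = y4d
    k4d = _accel(y4t, y4d, ss, extra, m, L, l, g, mu, k, a)

    y5t = th + h * (
        19372.0 / 6561.0 * k1t
        - 25360.0 / 2187.0 * k2t
        + 64448.0 / 6561.0 * k3t
        - 212.0 / 729.0 * k4t
    )
    y5d = thd + h * (
        19372.0 / 6561.0 * k1d
        - 25360.0 / 2187.0 * k2d
        + 64448.0 / 6561.0 * k3d
        - 212.0 / 729.0 * k4d
    )
    k5t = y5d
    k5d = _accel(y5t, y5d, ss, extra, m, L, l, g, mu, k, a)

    y6t = th + h * (
        9017.0 / 3168.0 * k1t
        - 355.0 / 33.0 * k2t
        + 46732.0 / 5247.0 * k3t
        + 49.0 / 176.0 * k4t
        - 5103.0 / 18656.0 * k5t
    )
    y6d = thd + h * (
        9017.0 / 3168.0 * k1d
        - 355.0 / 33.0 * k2d
        + 46732.0 / 5247.0 * k3d
        + 49.0 / 176.0 * k4d
        - 5103.0 / 18656.0 * k5d
    )
    k6t = y6d
    k6d = _accel(y6t, y6d, ss, extra, m, L, l, g, mu, k, a)

    # 5th-order solution
    th1 = th + h * (
        35.0 / 384.0 * k1t
        + 500.0 / 1113.0 * k3t
        + 125.0 / 192.0 * k4t
        - 2187.0 / 6784.0 * k5t
        + 11.0 / 84.0 * k6t
    )
    thd1 = thd + h * (
        35.0 / 384.0 * k1d
        + 500.0 / 1113.0 * k3d
        + 125.0 / 192.0 * k4d
        - 2187.0 / 6784.0 * k5d
        + 11.0 / 84.0 * k6d
    )
    k7t = thd1
    k7d = _accel(th1, thd1, ss, extra, m, L, l, g, mu, k, a)

    # embedded 4th-order solution for the error estimate
    th4 = th + h * (
        5179.0 / 57600.0 * k1t
        + 7571.0 / 16695.0 * k3t
        + 393.0 / 640.0 * k4t
        - 92097.0 / 339200.0 * k5t
        + 187.0 / 2100.0 * k6t
        + 1.0 / 40.0 * k7t
    )
    thd4 = thd + h * (
        5179.0 / 57600.0 * k1d
        + 7571.0 / 16695.0 * k3d
        + 393.0 / 640.0 * k4d
        - 92097.0 / 339200.0 * k5d
        + 187.0 / 2100.0 * k6d
        + 1.0 / 40.0 * k7d
    )
    e1 = th1 - th4
    e2 = thd1 - thd4
    err = np.sqrt(0.5 * (e1 * e1 + e2 * e2))
    return th1, thd1, err


@njit(cache=True, inline="always")
def _hermite(s, h, y0, d0, y1, d1):
    """Cubic Hermite interpolant on [0, 1] with endpoint values and slopes*h."""
    s2 = s * s
    s3 = s2 * s
    return (
        (2.0 * s3 - 3.0 * s2 + 1.0) * y0
        + (s3 - 2.0 * s2 + s) * h * d0
        + (-2.0 * s3 + 3.0 * s2) * y1
        + (s3 - s2) * h * d1
    )


@njit(cache=True)
def _locate_theta(target, h, th0, thd0, th1, thd1):
    """Bisect s in [0, 1] where the Hermite interpolant of theta hits target."""
    lo, hi = 0.0, 1.0
    flo = th0 - target
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        fm = _hermite(mid, h, th0, thd0, th1, thd1) - target
        if (fm > 0.0) == (flo > 0.0):
            lo = mid
            flo = fm
        else:
            hi = mid
    return 0.5 * (lo + hi)


@njit(cache=True)
def _locate_thd_zero(h, thd0, a0, thd1, a1):
    """Bisect s in [0, 1] where the Hermite interpolant of theta_dot crosses zero."""
    lo, hi = 0.0, 1.0
    flo = thd0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        fm = _hermite(mid, h, thd0, a0, thd1, a1)
        if (fm > 0.0) == (flo > 0.0):
            lo = mid
            flo = fm
        else:
            hi = mid
    return 0.5 * (lo + hi)


@njit(cache=True)
def sim_step(
    t0,
    th0,
    thd0,
    pulse_on_this_leg,
    A,
    width,
    tau_p,
    delta,
    policy,
    m,
    L,
    l,
    g,
    alpha,
    mu,
    k,
    a,
    theta_f,
    theta_cap,
    tol,
    rec_t,
    rec_th,
    rec_thd,
    rec_ph,
    rec_tp,
    n0,
):
    """Integrate one full step (double stance -> toe-off -> single stance -> heel strike).

    Starts at (t0, th0, thd0) in double stance and ends just after the
    heel-strike collision.  ``pulse_on_this_leg`` gates the square-pulse
    torque train (amplitude A, width, period tau_p, initial offset
    delta) onto this step's trailing ankle; it contributes only during
    double stance.  Under EXTEND_WHILE_POSITIVE a pulse still active at
    psi = mu keeps the trailing foot pushing (spring torque clamped to
    zero) until pulse-off or the linkage cap theta_cap.

    If ``rec_t.size > 0``, accepted points and events are appended to
    the recording arrays starting at index n0 (columns: time, theta,
    theta_dot, phase code 0/2, applied pulse torque).

    Returns
    -------
    (status, t_toe, t_heel, thd_toe, thd_pre, thd_post, pulse_work,
     min_FB, min_f, n_rec)
    """
    record = rec_t.size > 0
    t = t0
    th = th0
    thd = thd0
    nrec = n0
    status = -1
    t_toe = np.nan
    t_heel = np.nan
    thd_toe = np.nan
    thd_pre = np.nan
    thd_post = np.nan
    work = 0.0
    min_FB = _INF
    min_f = _INF

    # pulse bookkeeping
    pulsed = pulse_on_this_leg and A > 0.0
    on = False
    t_switch = _INF
    if pulsed:
        ph = (t - delta) % tau_p
        on = ph < width
        t_switch = t + (width - ph if on else tau_p - ph)
    extra = A if on else 0.0
    psi_seg = _psi(th, L, l, a)  # pulse-work segment start (used while on)
    extending = False

    if thd >= 0.0:
        # degenerate start: no forward progression
        return FALL_BACK, t_toe, t_heel, thd_toe, thd_pre, thd_post, work, min_FB, min_f, nrec

    fb = _grf_leading(th, thd, extra, m, L, l, g, mu, k, a)
    if fb < min_FB:
        min_FB = fb
    if record:
        rec_t[nrec] = t
        rec_th[nrec] = th
        rec_thd[nrec] = thd
        rec_ph[nrec] = 0.0
        rec_tp[nrec] = extra
        nrec += 1

    h = 1e-3
    # ---------------- double stance (possibly extended) ----------------
    for _ in range(_MAX_STEPS):
        if status >= 0:
            break
        hs = h
        hit_switch = False
        if t_switch - t <= hs:
            hs = t_switch - t
            hit_switch = True
            if hs <= 0.0:
                hs = 1e-15
        th1, thd1, err = _dp_step(t, th, thd, hs, False, extra, m, L, l, g, mu, k, a)
        if err > tol and hs > 1e-13:
            h = max(hs * max(0.2, 0.9 * (tol / err) ** 0.2), 1e-13)
            continue

        a0 = _accel(th, thd, False, extra, m, L, l, g, mu, k, a)
        a1 = _accel(th1, thd1, False, extra, m, L, l, g, mu, k, a)

        # earliest event within the accepted step
        s_ev = 2.0
        ev = -1
        if thd1 >= 0.0:
            s = _locate_thd_zero(hs, thd, a0, thd1, a1)
            if s < s_ev:
                s_ev = s
                ev = 1  # fall-back
        tgt = theta_cap if extending else theta_f
        if th1 <= tgt:
            s = _locate_theta(tgt, hs, th, thd, th1, thd1)
            if s < s_ev:
                s_ev = s
                ev = 0  # toe-off boundary (or extension cap)

        if ev >= 0:
            te = t + s_ev * hs
            the = tgt if ev == 0 else _hermite(s_ev, hs, th, thd, th1, thd1)
            thde = _hermite(s_ev, hs, thd, a0, thd1, a1)
            if ev == 1:
                t = te
                th = the
                thd = thde
                status = FALL_BACK
                if record:
                    rec_t[nrec] = t
                    rec_th[nrec] = th
                    rec_thd[nrec] = thd
                    rec_ph[nrec] = 0.0
                    rec_tp[nrec] = extra
                    nrec += 1
                break
            # toe-off boundary reached
            t = te
            th = the
            thd = thde
            if (not extending) and on and policy == EXTEND_WHILE_POSITIVE:
                # keep pushing on the pulse alone past psi = mu
                extending = True
                if record:
                    rec_t[nrec] = t
                    rec_th[nrec] = th
                    rec_thd[nrec] = thd
                    rec_ph[nrec] = 0.0
                    rec_tp[nrec] = extra
                    nrec += 1
                h = min(h, 1e-3)
                continue
            # genuine toe-off (nominal, or forced at the linkage cap)
            if on:
                work += A * (_psi(th, L, l, a) - psi_seg)
                on = False  # pulse nullified once the leg is in swing
            t_toe = t
            thd_toe = thd
            fb = _grf_leading(th, thd, extra, m, L, l, g, mu, k, a)
            if fb < min_FB:
                min_FB = fb
            if record:
                rec_t[nrec] = t
                rec_th[nrec] = th
                rec_thd[nrec] = thd
                rec_ph[nrec] = 0.0
                rec_tp[nrec] = extra if not extending else A
                nrec += 1
            break

        # plain accepted step
        t = t + hs
        th = th1
        thd = thd1
        if err > 0.0:
            fac = 0.9 * (tol / err) ** 0.2
            if fac > 5.0:
                fac = 5.0
            h = hs * fac
        else:
            h = hs * 5.0
        fb = _grf_leading(th, thd, extra, m, L, l, g, mu, k, a)
        if fb < min_FB:
            min_FB = fb
        if record:
            rec_t[nrec] = t
            rec_th[nrec] = th
            rec_thd[nrec] = thd
            rec_ph[nrec] = 0.0
            rec_tp[nrec] = extra
            nrec += 1

        if hit_switch:
            if on:
                # pulse off
                work += A * (_psi(th, L, l, a) - psi_seg)
                on = False
                extra = 0.0
                if extending:
                    # extension ends when the pushing torque vanishes
                    t_toe = t
                    thd_toe = thd
                    fb = _grf_leading(th, thd, 0.0, m, L, l, g, mu, k, a)
                    if fb < min_FB:
                        min_FB = fb
                    break
                t_switch = t + (tau_p - width)
            else:
                on = True
                extra = A
                psi_seg = _psi(th, L, l, a)
                t_switch = t + width

    if status == FALL_BACK:
        thd_post = thd
        return status, t_toe, t_heel, thd_toe, thd_pre, thd_post, work, min_FB, min_f, nrec
    if not np.isfinite(t_toe):
        return MAXITER, t_toe, t_heel, thd_toe, thd_pre, thd_post, work, min_FB, min_f, nrec

    # ---------------- single stance (inverted pendulum) ----------------
    f = m * (g * np.cos(th) - L * thd * thd)
    if f < min_f:
        min_f = f
    if record:
        rec_t[nrec] = t
        rec_th[nrec] = th
        rec_thd[nrec] = thd
        rec_ph[nrec] = 2.0
        rec_tp[nrec] = 0.0
        nrec += 1
    h = 1e-3
    for _ in range(_MAX_STEPS):
        th1, thd1, err = _dp_step(t, th, thd, h, True, 0.0, m, L, l, g, mu, k, a)
        if err > tol and h > 1e-13:
            h = max(h * max(0.2, 0.9 * (tol / err) ** 0.2), 1e-13)
            continue
        a0 = _accel(th, thd, True, 0.0, m, L, l, g, mu, k, a)
        a1 = _accel(th1, thd1, True, 0.0, m, L, l, g, mu, k, a)
        s_ev = 2.0
        ev = -1
        if thd1 >= 0.0:
            s = _locate_thd_zero(h, thd, a0, thd1, a1)
            if s < s_ev:
                s_ev = s
                ev = 1
        if th1 <= -alpha:
            s = _locate_theta(-alpha, h, th, thd, th1, thd1)
            if s < s_ev:
                s_ev = s
                ev = 0
        if ev >= 0:
            te = t + s_ev * h
            thde = _hermite(s_ev, h, thd, a0, thd1, a1)
            if ev == 1:
                t = te
                th = _hermite(s_ev, h, th, thd, th1, thd1)
                thd = thde
                status = FALL_BACK
                thd_post = thd
                if record:
                    rec_t[nrec] = t
                    rec_th[nrec] = th
                    rec_thd[nrec] = thd
                    rec_ph[nrec] = 2.0
                    rec_tp[nrec] = 0.0
                    nrec += 1
                break
            # heel strike: inelastic collision, speed scaled by cos(2*alpha)
            t = te
            th = -alpha
            thd = thde
            t_heel = t
            thd_pre = thd
            thd_post = np.cos(2.0 * alpha) * thd
            status = COMPLETED
            f = m * (g * np.cos(th) - L * thd * thd)
            if f < min_f:
                min_f = f
            if record:
                rec_t[nrec] = t
                rec_th[nrec] = th
                rec_thd[nrec] = thd
                rec_ph[nrec] = 2.0
                rec_tp[nrec] = 0.0
                nrec += 1
            break
        t = t + h
        th = th1
        thd = thd1
        if err > 0.0:
            fac = 0.9 * (tol / err) ** 0.2
            if fac > 5.0:
                fac = 5.0
            h = h * fac
        else:
            h = h * 5.0
        f = m * (g * np.cos(th) - L * thd * thd)
        if f < min_f:
            min_f = f
        if record:
            rec_t[nrec] = t
            rec_th[nrec] = th
            rec_thd[nrec] = thd
            rec_ph[nrec] = 2.0
            rec_tp[nrec] = 0.0
            nrec += 1
    if status < 0:
        status = MAXITER
    return status, t_toe, t_heel, thd_toe, thd_pre, thd_post, work, min_FB, min_f, nrec


@njit(cache=True)
def sim_walk(
    n_steps,
    thd0,
    perturbed_parity,
    A,
    width,
    tau_p,
    delta,
    policy,
    m,
    L,
    l,
    g,
    alpha,
    mu,
    k,
    a,
    theta_f,
    theta_cap,
    tol,
    out,
):
    """Chain up to n_steps steps from the post-collision state (alpha, thd0) at t = 0.

    The trailing-leg parity of step i is i % 2; the pulse train acts
    only on steps whose trailing parity equals ``perturbed_parity``.
    Fills ``out`` (n_steps x 10) with per-step rows
    (status, t_start, t_toe, t_heel, thd_start, thd_pre, thd_post,
    pulse_work, min_FB, min_f) and returns the number of completed rows;
    stops early on any non-COMPLETED step.
    """
    empty = np.empty(0, dtype=np.float64)
    t = 0.0
    thd = thd0
    n_done = 0
    for i in range(n_steps):
        active = (i % 2) == perturbed_parity
        (
            status,
            t_toe,
            t_heel,
            _thd_toe,
            thd_pre,
            thd_post,
            work,
            min_FB,
            min_f,
            _n,
        ) = sim_step(
            t,
            alpha,
            thd,
            active,
            A,
            width,
            tau_p,
            delta,
            policy,
            m,
            L,
            l,
            g,
            alpha,
            mu,
            k,
            a,
            theta_f,
            theta_cap,
            tol,
            empty,
            empty,
            empty,
            empty,
            empty,
            0,
        )
        out[i, 0] = status
        out[i, 1] = t
        out[i, 2] = t_toe
        out[i, 3] = t_heel
        out[i, 4] = thd
        out[i, 5] = thd_pre
        out[i, 6] = thd_post
        out[i, 7] = work
        out[i, 8] = min_FB
        out[i, 9] = min_f
        n_done = i + 1
        if status != COMPLETED:
            break
        t = t_heel
        thd = thd_post
    return n_done
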