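"""Independent brute-force re-evaluation of the table-activity rules.

Deliberately written as plain frame-by-frame Python over shapely Point
objects, sharing no code with the package's classifier, so agreement
between the two is evidence that the vectorized implementation encodes the
written rules and not the other way round.
"""

import math

from shapely.geometry import Point


def _kp(pose, name, min_conf):
    from orpose.io import KEYPOINT_INDEX

    x, y, c = pose.keypoints[KEYPOINT_INDEX[name]]
    if math.isnan(x) or math.isnan(y) or math.isnan(c) or c < min_conf:
        return None
    return (float(x), float(y))


def _head(pose, min_conf):
    pts = [
        p
        for name in ("nose", "left_eye", "right_eye", "left_ear", "right_ear")
        if (p := _kp(pose, name, min_conf)) is not None
    ]
    if not pts:
        return None
    return (
        sum(p[0] for p in pts) / len(pts),
        sum(p[1] for p in pts) / len(pts),
    )


def brute_force_classify(track, zones, threshold=17.5, window=5, min_conf=0.3):
    """Status per frame of the track, as a dict frame -> str."""
    out = {}
    for t in sorted(track.poses):
        pose = track.poses[t]
        lw = _kp(pose, "left_wrist", min_conf)
        rw = _kp(pose, "right_wrist", min_conf)
        ls = _kp(pose, "left_shoulder", min_conf)
        rs = _kp(pose, "right_shoulder", min_conf)
        hd = _head(pose, min_conf)

        if None in (lw, rw, ls, rs) or hd is None:
            zone = "undetermined"
        elif (
            zones.wrist_zone.covers(Point(lw))
            and zones.wrist_zone.covers(Point(rw))
            and zones.shoulder_zone.covers(Point(ls))
            and zones.shoulder_zone.covers(Point(rs))
            and zones.head_zone.covers(Point(hd))
        ):
            zone = "pass"
        else:
            zone = "fail"

        disp = None
        if t >= window and (t - window) in track.poses:
            prev = track.poses[t - window]
            pls = _kp(prev, "left_shoulder", min_conf)
            prs = _kp(prev, "right_shoulder", min_conf)
            phd = _head(prev, min_conf)
            if None not in (ls, rs, pls, prs) and hd is not None and phd is not None:
                dists = [
                    math.dist(ls, pls),
                    math.dist(rs, prs),
                    math.dist(hd, phd),
                ]
                disp = sum(dists) / 3.0

        if zone == "fail":
            out[t] = "inactive"
        elif disp is not None and disp > threshold:
            out[t] = "inactive"
        elif zone == "undetermined" or disp is None:
            out[t] = "undetermined"
        else:
            out[t] = "active"
    return out
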