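"""Classify smoke days from plume polygons overlapping the catchment.

Builds the default ~18,719 km² four-county-style study area and three plume
disks — one large, one marginal, one far away — and classifies a week of
days with the 1 km² overlap threshold.
"""

from shapely.geometry import Point

from smokeqol.geometry import PlumeRecord, default_study_area, detect_smoke_days

area = default_study_area()
print(f"study area: {area.name}, {area.total_area:,.0f} km²")

mk = area.projection.unproject
plumes = [
    PlumeRecord("2011-06-06", mk(Point(0, 0).buffer(90.0))),       # broad smoke event
    PlumeRecord("2011-06-07", mk(Point(95, 0).buffer(30.0))),      # grazing the boundary
    PlumeRecord("2011-06-08", mk(Point(500, 0).buffer(60.0))),     # distant plume
]
table = detect_smoke_days(plumes, area, "2011-06-05", "2011-06-09")
print(table)
# A day is a smoke day when unioned plume-catchment overlap is >= 1 km²;
# overlap_km2 is the coverage that also feeds the cumulative-area exposure metric.
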