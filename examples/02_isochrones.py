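"""Ambulance service areas (isochrones) on the synthetic city.

Classifies every 500 m grid cell by ideal-condition travel time from the
nearest ambulance base into <=5 / <=10 / <=15 / >15 min bands and prints
the area of each band in km^2.
"""

from ohca_coverage import (
    aggregate_demand,
    band_areas,
    filter_events,
    generate_city,
    simulate_events,
    travel_time_field,
)

city = generate_city(seed=1)
events = filter_events(simulate_events(city, 476, seed=1))
grid = aggregate_demand(events, 500.0, bbox=city.bbox)

field = travel_time_field(city, grid)
for band, area in band_areas(field).items():
    print(f"  {band:>8}: {area / 1e6:6.2f} km^2")

# Under ideal free-flow conditions almost the whole city sits inside the
# 5-min band; compare with the realistic field, which adds the median
# dispatch delay and average congestion:
real = travel_time_field(city, grid, realistic=True)
areas = band_areas(real)
print("with dispatch delay and congestion:")
for band, area in areas.items():
    print(f"  {band:>8}: {area / 1e6:6.2f} km^2")
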