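"""Synthetic nearshore shelf environment.

The world is a north-south coastline (a meridional line with a sinusoidal
perturbation) with a shelf whose depth increases linearly with distance from
shore. Everything is built in a local equal-area km frame centred on the
configured deployment region; lon/lat interfaces convert through that frame.

The environment exposes the three geometric objects the pipeline filters
depend on:

* the land polygon and its 1-km inland tolerance strip (Argos error allowance),
* a bathymetry raster (m below sea level, positive down, north-up),
* the "shallow-shelf" constraint region: ocean shallower than the 100-m
  isobath plus the 1-km inland strip, which bounds both the depth filter and
  the constrained random walks of the site-fidelity test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon, box, mapping, shape

from .config import SimConfig
from .geometry import LambertAzimuthalEqualArea

#: Depth value reported for points on land (beyond the raster's ocean ramp).
LAND_DEPTH_SENTINEL = -9999.0


@dataclass
class BathymetryGrid:
    """North-up raster of water depth (m, positive down) in the local km frame.

    ``values[0, 0]`` is the north-west cell; ``x0, y0`` is the outer corner
    of that cell and ``cell_km`` the (square) cell size.
    """

    x0: float
    y0: float
    cell_km: float
    values: np.ndarray  # (nrows, ncols)

    @property
    def shape(self):
        return self.values.shape

    def cell_centers(self):
        nr, nc = self.values.shape
        xc = self.x0 + (np.arange(nc) + 0.5) * self.cell_km
        yc = self.y0 - (np.arange(nr) + 0.5) * self.cell_km
        return xc, yc

    def sample_bilinear(self, x, y):
        """Bilinearly interpolated depth at km coordinates (clipped to extent)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        nr, nc = self.values.shape
        fx = (x - self.x0) / self.cell_km - 0.5
        fy = (self.y0 - y) / self.cell_km - 0.5
        fx = np.clip(fx, 0.0, nc - 1.0)
        fy = np.clip(fy, 0.0, nr - 1.0)
        i0 = np.clip(np.floor(fy).astype(int), 0, nr - 2) if nr > 1 else np.zeros_like(fy, int)
        j0 = np.clip(np.floor(fx).astype(int), 0, nc - 2) if nc > 1 else np.zeros_like(fx, int)
        ty = fy - i0
        tx = fx - j0
        v = self.values
        top = v[i0, j0] * (1 - tx) + v[i0, j0 + 1] * tx
        bot = v[i0 + 1, j0] * (1 - tx) + v[i0 + 1, j0 + 1] * tx
        return top * (1 - ty) + bot * ty

    def in_extent(self, x, y):
        nr, nc = self.values.shape
        return ((np.asarray(x) >= self.x0) & (np.asarray(x) <= self.x0 + nc * self.cell_km)
                & (np.asarray(y) <= self.y0) & (np.asarray(y) >= self.y0 - nr * self.cell_km))

    def write_ascii(self, path):
        """Write as an ESRI ASCII grid (units: km origin, m depth)."""
        nr, nc = self.values.shape
        header = (f"ncols {nc}\nnrows {nr}\n"
                  f"xllcorner {self.x0}\nyllcorner {self.y0 - nr * self.cell_km}\n"
                  f"cellsize {self.cell_km}\nNODATA_value {LAND_DEPTH_SENTINEL}\n")
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.values, fmt="%.3f")

    @classmethod
    def read_ascii(cls, path):
        meta = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            values = np.loadtxt(fh)
        nr = int(meta["nrows"])
        values = values.reshape(nr, int(meta["ncols"]))
        cell = meta["cellsize"]
        return cls(x0=meta["xllcorner"], y0=meta["yllcorner"] + nr * cell,
                   cell_km=cell, values=values)


@dataclass
class Environment:
    """Shelf world: land geometry, bathymetry, and derived constraint regions.

    All polygons are stored in the local equal-area km frame (``proj``);
    helpers accept lon/lat and convert.
    """

    proj: LambertAzimuthalEqualArea
    land: Polygon
    ocean: Polygon
    coastline: LineString
    ocean_buffer_1km: Polygon          # ocean plus the 1-km inland strip
    isobath_region: Polygon            # depth <= max_depth_m ocean + inland strip
    bathymetry: BathymetryGrid
    shelf_slope_m_per_km: float
    max_depth_m: float = 100.0

    # -- coordinate helpers -------------------------------------------------
    def to_xy(self, lon, lat):
        return self.proj.forward(lon, lat)

    def to_lonlat(self, x, y):
        return self.proj.inverse(x, y)

    # -- queries ------------------------------------------------------------
    def is_land(self, lon, lat):
        x, y = self.to_xy(lon, lat)
        pts = shapely.points(np.column_stack([np.atleast_1d(x), np.atleast_1d(y)]))
        out = shapely.contains(self.land, pts)
        return out if np.ndim(lon) else bool(out[0])

    def depth_m(self, lon, lat):
        """Sampled depth at lon/lat; land points get ``LAND_DEPTH_SENTINEL``."""
        x, y = self.to_xy(lon, lat)
        d = self.bathymetry.sample_bilinear(x, y)
        land = self.is_land(np.atleast_1d(lon), np.atleast_1d(lat))
        d = np.where(land, LAND_DEPTH_SENTINEL, np.maximum(d, 0.0))
        return d if np.ndim(lon) else float(d if np.isscalar(d) else np.asarray(d).ravel()[0])

    def distance_to_land_km(self, lon, lat):
        """Great-circle-equivalent distance to the nearest land, km (0 on land)."""
        x, y = self.to_xy(lon, lat)
        pts = shapely.points(np.column_stack([np.atleast_1d(x), np.atleast_1d(y)]))
        d = shapely.distance(pts, self.land)
        return d if np.ndim(lon) else float(d[0])

    def inland_distance_km(self, lon, lat):
        """Distance from a land point to the ocean, km (0 in the ocean)."""
        x, y = self.to_xy(lon, lat)
        pts = shapely.points(np.column_stack([np.atleast_1d(x), np.atleast_1d(y)]))
        d = shapely.distance(pts, self.ocean)
        return d if np.ndim(lon) else float(d[0])

    def in_ocean_xy(self, x, y):
        pts = shapely.points(np.column_stack([np.atleast_1d(x), np.atleast_1d(y)]))
        return shapely.contains(self.ocean, pts)

    def in_isobath_region_xy(self, x, y):
        pts = shapely.points(np.column_stack([np.atleast_1d(x), np.atleast_1d(y)]))
        return shapely.contains(self.isobath_region, pts)

    def covers(self, lon, lat):
        x, y = self.to_xy(lon, lat)
        return self.bathymetry.in_extent(x, y)

    # -- I/O ----------------------------------------------------------------
    def _poly_lonlat(self, geom):
        def ring(coords):
            xs, ys = np.array(coords).T
            lon, lat = self.to_lonlat(xs, ys)
            return [list(p) for p in zip(lon.tolist(), lat.tolist())]

        if geom.geom_type == "Polygon":
            return {"type": "Polygon",
                    "coordinates": [ring(geom.exterior.coords)]
                    + [ring(i.coords) for i in geom.interiors]}
        return {"type": "MultiPolygon",
                "coordinates": [self._poly_lonlat(g)["coordinates"] for g in geom.geoms]}

    def write_geojson(self, path):
        feats = []
        for name, geom in (("land", self.land),
                           ("ocean_buffer_1km", self.ocean_buffer_1km),
                           ("isobath_region", self.isobath_region)):
            feats.append({"type": "Feature", "properties": {"name": name},
                          "geometry": self._poly_lonlat(geom)})
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


def build_environment(config: SimConfig) -> Environment:
    """Construct the synthetic shelf world for a simulation config.

    The coast runs north-south at local x = A sin(2 pi y / wavelength); land
    lies west (x below the curve), ocean east. Depth on the shelf rises
    linearly with distance from the coastline at ``shelf_slope_m_per_km``,
    so the 100-m isobath sits 100/slope km offshore.
    """
    if config.shelf_slope_m_per_km <= 0 or config.domain_offshore_km <= 0:
        raise ValueError("invalid shelf slope or extent")

    proj = LambertAzimuthalEqualArea(config.center_lon, config.center_lat)
    half_span_km = config.domain_lat_span_deg * 111.195 / 2.0
    amp = config.coast_amplitude_km
    wav = config.coast_wavelength_km
    land_margin = amp + 15.0

    ys = np.arange(-half_span_km, half_span_km + 0.25, 0.25)
    coast_x = amp * np.sin(2.0 * np.pi * ys / wav) if amp > 0 else np.zeros_like(ys)
    coastline = LineString(np.column_stack([coast_x, ys]))

    domain = box(-land_margin, -half_span_km, config.domain_offshore_km, half_span_km)
    land_ring = ([(-land_margin, -half_span_km)]
                 + list(zip(coast_x, ys))
                 + [(-land_margin, half_span_km)])
    land = Polygon(land_ring).intersection(domain)
    ocean = domain.difference(land)

    strip_in = land.intersection(shapely.buffer(coastline, 1.0))
    ocean_buffer = shapely.union(ocean, strip_in)

    iso_off_km = 100.0 / config.shelf_slope_m_per_km
    iso_ocean = ocean.intersection(shapely.buffer(coastline, iso_off_km))
    isobath_region = shapely.union(iso_ocean, strip_in)

    # bathymetry raster: depth = slope * distance to coastline over ocean,
    # clamped to 0 on land so bilinear sampling stays continuous at the coast
    cell = config.raster_cell_km
    x0, y0 = -land_margin, half_span_km
    nc = int(np.ceil((config.domain_offshore_km + land_margin) / cell))
    nr = int(np.ceil(2 * half_span_km / cell))
    xc = x0 + (np.arange(nc) + 0.5) * cell
    yc = y0 - (np.arange(nr) + 0.5) * cell
    gx, gy = np.meshgrid(xc, yc)
    pts = shapely.points(np.column_stack([gx.ravel(), gy.ravel()]))
    dist = shapely.distance(pts, coastline).reshape(nr, nc)
    coast_at = amp * np.sin(2.0 * np.pi * gy / wav) if amp > 0 else np.zeros_like(gy)
    offshore = gx > coast_at
    depth = np.where(offshore, config.shelf_slope_m_per_km * dist, 0.0)
    bathy = BathymetryGrid(x0=x0, y0=y0, cell_km=cell, values=depth)

    return Environment(proj=proj, land=land, ocean=ocean, coastline=coastline,
                       ocean_buffer_1km=ocean_buffer, isobath_region=isobath_region,
                       bathymetry=bathy,
                       shelf_slope_m_per_km=config.shelf_slope_m_per_km)


def read_geojson_features(path):
    """Read a GeoJSON FeatureCollection into (properties, shapely geometry) pairs."""
    with open(path) as fh:
        doc = json.load(fh)
    return [(f.get("properties", {}), shape(f["geometry"])) for f in doc["features"]]


def write_geojson_features(path, records):
    """Write (properties, shapely geometry) pairs as a GeoJSON FeatureCollection."""
    feats = [{"type": "Feature", "properties": props, "geometry": mapping(geom)}
             for props, geom in records]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
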