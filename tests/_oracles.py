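"""Independent brute-force evaluators used as oracles.

Everything here loops explicitly over the 16 rooms and four directions,
re-deriving each update from its definition; nothing is shared with the
package's vectorized implementations.
"""

import numpy as np

from tigermaze.maze_env import BACK, MazeConfig, Pose, abs_direction, turn


def oracle_tiger_dir(cell: int, orientation: int, maze: MazeConfig) -> int:
    """Relative tiger direction by explicit search over the four doors."""
    for rel in range(4):
        other = int(maze.nbr[cell, abs_direction(rel, orientation)])
        if frozenset((cell, other)) in maze.tiger_edges:
            return rel
    raise AssertionError("cell without tiger edge")


def oracle_listen_grid(p_grid, anchor, v, cond_map, d, beta, gamma, epsilon,
                       re_estimate, maze):
    """Listen-trial grid update by looping over all rooms.

    ``re_estimate`` selects the branch; ``cond_map`` is the MAP tiger
    direction conditioning the re-estimation weighting."""
    w_match = (1 - gamma) * beta + gamma * (1 - beta)
    w_mis = gamma * beta + (1 - gamma) * (1 - beta)

    def weigh(prior, target):
        out = np.zeros_like(prior)
        for c in range(maze.n_cells):
            td = oracle_tiger_dir(c, d, maze)
            if td == BACK:
                w = gamma
            elif td == target:
                w = w_match
            else:
                w = w_mis
            out[c] = w * prior[c]
        return out / out.sum()

    p_ud = weigh(p_grid, v)
    if not re_estimate:
        return p_ud
    p_re = weigh(anchor, cond_map)
    return (1 - epsilon) * p_re + epsilon * p_ud


def oracle_topdown_listen_grid(p_grid, v, d, gamma, alpha, maze):
    out = np.zeros_like(p_grid)
    for c in range(maze.n_cells):
        td = oracle_tiger_dir(c, d, maze)
        if td == BACK:
            w = gamma
        elif td == v:
            w = (1 - gamma) * alpha + gamma * (1 - alpha)
        else:
            w = gamma * alpha + (1 - gamma) * (1 - alpha)
        out[c] = w * p_grid[c]
    return out / out.sum()


def oracle_move_grid(p_grid, direction, d, maze):
    """Push-forward through the transition map, cell by cell."""
    out = np.zeros_like(p_grid)
    for c in range(maze.n_cells):
        d_new = abs_direction(direction, d)
        dest = int(maze.nbr[c, d_new])
        out[dest] += p_grid[c]
    return out


def oracle_tiger_marginal(p_grid, d, gamma, maze):
    """Tiger belief from the grid belief: (1-gamma) on each room's true
    direction, gamma/3 elsewhere (Back included), restricted to L/F/R."""
    p4 = np.zeros(4)
    for c in range(maze.n_cells):
        td = oracle_tiger_dir(c, d, maze)
        for s in range(4):
            p4[s] += ((1 - gamma) if s == td else gamma / 3) * p_grid[c]
    return p4[:3] / p4[:3].sum()


def oracle_parallel_tiger_move(p_tiger, direction, d, maze):
    """Tiger propagation through the enumerated direction-transition counts."""
    d_next = turn(d, direction)
    counts = np.zeros((3, 3))
    for c in range(maze.n_cells):
        i = oracle_tiger_dir(c, d, maze)
        if i == BACK:
            continue
        dest = int(maze.nbr[c, abs_direction(direction, d)])
        j = oracle_tiger_dir(dest, d_next, maze)
        if j != BACK:
            counts[i, j] += 1
    p = np.array(p_tiger, dtype=float)
    p[direction] = 0.0
    out = np.zeros(3)
    for i in range(3):
        rs = counts[i].sum()
        row = counts[i] / rs if rs > 0 else np.full(3, 1 / 3)
        out += p[i] * row
    return out / out.sum()


def oracle_exact_grid_filter(prior, roars, d, alpha, maze):
    """Exact Bayes filter over rooms for a listen-only stay in one room:
    rooms whose tiger door faces the agent's back are impossible (a roar
    was heard), matching rooms have likelihood alpha per roar, the rest
    (1 - alpha)/2."""
    p = np.array(prior, dtype=float)
    for v in roars:
        lik = np.zeros_like(p)
        for c in range(maze.n_cells):
            td = oracle_tiger_dir(c, d, maze)
            if td == BACK:
                lik[c] = 0.0
            elif td == v:
                lik[c] = alpha
            else:
                lik[c] = (1 - alpha) / 2
        p = p * lik
        p = p / p.sum()
    return p
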