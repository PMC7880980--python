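# Default English function-word stoplist (closed-class words only).
# Determiners, pronouns, prepositions, conjunctions, auxiliaries, particles.
# One word per line; lines starting with '#' are comments. User-replaceable.
the
an
and
or
but
nor
so
yet
for
of
in
on
at
by
to
from
with
without
within
into
onto
upon
about
above
below
under
over
between
among
through
throughout
during
before
after
since
until
till
toward
towards
across
along
around
behind
beside
besides
beyond
near
off
out
up
down
via
per
than
as
if
unless
although
though
because
while
whereas
whether
that
which
who
whom
whose
what
whatever
whoever
whichever
when
whenever
where
wherever
why
how
this
these
those
it
its
itself
he
him
his
himself
she
her
hers
herself
they
them
their
theirs
themselves
we
us
our
ours
ourselves
you
your
yours
yourself
yourselves
me
my
mine
myself
one
ones
oneself
be
am
is
are
was
were
been
being
have
has
had
having
do
does
did
doing
done
will
would
shall
should
can
could
may
might
must
ought
need
dare
not
no
nor
neither
either
both
each
every
all
any
some
none
few
many
much
more
most
less
least
several
such
same
other
another
again
also
too
very
quite
rather
just
only
even
still
ever
never
always
often
sometimes
then
there
here
now
once
twice
yes
oh
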