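abbreviation,expansion
gr8,great
b4,before
l8r,later
u,you
ur,your
r,are
thx,thanks
ty,thanks
pls,please
plz,please
msg,message
txt,text
luv,love
omg,oh my god
idk,i do not know
imo,in my opinion
imho,in my opinion
btw,by the way
tbh,to be honest
fyi,for your information
dr,doctor
doc,doctor
appt,appointment
meds,medication
rx,prescription
yr,year
yrs,years
hr,hour
hrs,hours
tmrw,tomorrow
2day,today
2moro,tomorrow
gonna,going to
wanna,want to
gotta,got to
cuz,because
bc,because
im,i am
dont,do not
cant,can not
wont,will not
didnt,did not
doesnt,does not
isnt,is not
wasnt,was not
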